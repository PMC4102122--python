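"""Slab occupancy counting, histograms, summaries and density grids."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydrogate as hg

from conftest import REF_EXPR


def _frame_at(z_list, box=100.0):
    coords = np.array([[50.0, 50.0, 50.0 + z] for z in z_list])
    return hg.Frame(0.0, coords, np.array([box] * 3))


ORIGIN_PF = hg.PoreFrame(origin=np.array([50.0, 50.0, 50.0]),
                         axis=np.array([0.0, 0.0, 1.0]))


class TestSlabCount:
    def test_direct_containment(self):
        frame = _frame_at([-6.0, -7.0, -12.0])
        sel = hg.AtomSelection(np.arange(3))
        region = hg.SlabRegion(-10.0, -5.0)
        assert hg.count_waters_in_slab(frame, sel, ORIGIN_PF, region) == 2

    def test_half_open_bounds(self):
        frame = _frame_at([-5.0, -10.0])
        sel = hg.AtomSelection(np.arange(2))
        region = hg.SlabRegion(-10.0, -5.0)
        # upper bound excluded, lower included
        assert hg.count_waters_in_slab(frame, sel, ORIGIN_PF, region) == 1

    def test_radial_cutoff(self):
        coords = np.array([[50.0, 50.0, 43.0],   # on axis, in slab
                           [58.0, 50.0, 43.0]])  # 8 Å off axis, same z
        frame = hg.Frame(0.0, coords, np.array([100.0] * 3))
        sel = hg.AtomSelection(np.arange(2))
        assert hg.count_waters_in_slab(
            frame, sel, ORIGIN_PF, hg.SlabRegion(-10, -5)) == 2
        assert hg.count_waters_in_slab(
            frame, sel, ORIGIN_PF, hg.SlabRegion(-10, -5, radial_cutoff=5.0)) == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 200)
        coords = rng.uniform(30, 70, size=(n, 3))
        frame = hg.Frame(0.0, coords, np.array([100.0] * 3))
        sel = hg.AtomSelection(np.arange(n))
        region = hg.SlabRegion(-10.0, -5.0)
        expected = sum(1 for p in coords if -10.0 <= p[2] - 50.0 < -5.0)
        assert hg.count_waters_in_slab(frame, sel, ORIGIN_PF, region) == expected

    def test_empty_selection_policy(self):
        frame = _frame_at([-6.0])
        empty = hg.AtomSelection(np.array([], dtype=int))
        region = hg.SlabRegion(-10, -5)
        with pytest.raises(ValueError):
            hg.count_waters_in_slab(frame, empty, ORIGIN_PF, region)
        assert hg.count_waters_in_slab(frame, empty, ORIGIN_PF, region,
                                       empty_ok=True) == 0

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            hg.SlabRegion(-5.0, -10.0)


class TestOccupancySeries:
    def test_always_wet_mean_matches_poisson_intensity(self):
        spec = hg.PoreSpec()
        params = hg.WettingParams(k_dry=0.0, k_wet=1.0, lambda_full=12.0,
                                  n_frames=3000, seed=8)
        traj, _ = hg.gen_wetting_trajectory(spec, params)
        series = hg.occupancy_series(traj, hg.water_oxygens(traj.structure),
                                     hg.select(traj.structure, REF_EXPR),
                                     hg.SlabRegion(-10, -5))
        se = np.sqrt(12.0 / len(series))
        assert abs(series.counts.mean() - 12.0) < 3 * se

    def test_stride_is_subsampling(self, telegraph_run):
        _params, traj, _states, series = telegraph_run
        water = hg.water_oxygens(traj.structure)
        ref = hg.select(traj.structure, REF_EXPR)
        strided = hg.occupancy_series(traj, water, ref,
                                      hg.SlabRegion(-10, -5), stride=2)
        assert np.array_equal(strided.counts, series.counts[::2])
        assert np.array_equal(strided.times, series.times[::2])

    def test_rigid_translation_invariance(self):
        spec = hg.PoreSpec()
        params = hg.WettingParams(n_frames=40, seed=17)
        traj, _ = hg.gen_wetting_trajectory(spec, params)
        water = hg.water_oxygens(traj.structure)
        ref = hg.select(traj.structure, REF_EXPR)
        region = hg.SlabRegion(-10, -5)
        base = hg.occupancy_series(traj, water, ref, region)
        shifted = hg.Trajectory(
            structure=hg.Structure(
                names=traj.structure.names, residue_names=traj.structure.residue_names,
                residue_ids=traj.structure.residue_ids, chains=traj.structure.chains,
                elements=traj.structure.elements, vdw_radii=traj.structure.vdw_radii,
                coordinates=traj.structure.coordinates + np.array([3.0, -2.0, 9.0]),
                box=traj.structure.box),
            times=traj.times, box=traj.box,
            moving_indices=traj.moving_indices,
            moving_coords=traj.moving_coords + np.array([3.0, -2.0, 9.0]))
        moved = hg.occupancy_series(shifted, water, ref, region)
        assert np.array_equal(base.counts, moved.counts)


class TestHistogram:
    def test_small_example(self):
        s = hg.OccupancySeries(times=0.1 * np.arange(4),
                               counts=np.array([0, 0, 1, 2]),
                               region=hg.SlabRegion(-10, -5))
        h = hg.occupancy_histogram(s)
        assert h.probability_of(0) == pytest.approx(0.5)
        assert h.probability_of(1) == pytest.approx(0.25)
        assert h.probability_of(2) == pytest.approx(0.25)
        assert h.n_frames == 4

    def test_pooling_identical_series_keeps_probabilities(self):
        s = hg.OccupancySeries(times=0.1 * np.arange(4),
                               counts=np.array([0, 0, 1, 2]),
                               region=hg.SlabRegion(-10, -5))
        h1 = hg.occupancy_histogram(s)
        h2 = hg.occupancy_histogram([s, s])
        assert np.allclose(h1.probabilities, h2.probabilities)
        assert h2.n_frames == 8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=1, max_size=200))
    def test_probabilities_normalized_and_p0_is_fraction_zero(self, counts):
        s = hg.OccupancySeries(times=0.1 * np.arange(len(counts)),
                               counts=np.array(counts),
                               region=hg.SlabRegion(-10, -5))
        h = hg.occupancy_histogram(s)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        summ = hg.summarize_occupancy(s)
        assert summ.fraction_zero == pytest.approx(h.probability_of(0))

    def test_telegraph_p_zero_matches_stationary_law(self, telegraph_run):
        params, _traj, _states, series = telegraph_run
        h = hg.occupancy_histogram(series)
        lam = params.lambda_full
        expected = params.dry_fraction + np.exp(-lam) * (1 - params.dry_fraction)
        assert abs(h.probability_of(0) - expected) < 3 * params.dry_fraction_se()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hg.occupancy_histogram([])


class TestSummary:
    def test_small_example(self):
        s = hg.OccupancySeries(times=0.1 * np.arange(4),
                               counts=np.array([0, 0, 1, 2]),
                               region=hg.SlabRegion(-10, -5))
        summ = hg.summarize_occupancy(s)
        assert summ.mu == pytest.approx(0.75)
        assert summ.fraction_zero == pytest.approx(0.5)
        dry = [e for e in summ.dwell_episodes if e.state == "dry"]
        assert len(dry) == 1
        assert dry[0].duration == pytest.approx(0.2)
        assert dry[0].censored  # touches the series start

    def test_identical_partner_gives_zero_delta(self):
        s = hg.OccupancySeries(times=0.1 * np.arange(4),
                               counts=np.array([0, 0, 1, 2]),
                               region=hg.SlabRegion(-10, -5))
        assert hg.summarize_occupancy(s, partner=s).delta_mu == 0.0

    def test_wet_vs_dry_generators_recover_intensity_difference(self):
        spec = hg.PoreSpec()
        wet_p = hg.WettingParams(k_dry=0.0, k_wet=1.0, lambda_full=12.0,
                                 n_frames=3000, seed=21)
        dry_p = hg.WettingParams(k_dry=1.0, k_wet=0.0, n_frames=3000,
                                 seed=22, initial_state="dry")
        region = hg.SlabRegion(-10, -5)
        out = []
        for p in (wet_p, dry_p):
            traj, _ = hg.gen_wetting_trajectory(spec, p)
            out.append(hg.occupancy_series(
                traj, hg.water_oxygens(traj.structure),
                hg.select(traj.structure, REF_EXPR), region))
        summ = hg.summarize_occupancy(out[0], partner=out[1])
        se = np.sqrt(12.0 / 3000)
        assert abs(summ.delta_mu - 12.0) < 3 * se

    def test_mismatched_frame_spacing_rejected(self):
        a = hg.OccupancySeries(times=0.1 * np.arange(4),
                               counts=np.zeros(4, dtype=int),
                               region=hg.SlabRegion(-10, -5))
        b = hg.OccupancySeries(times=0.2 * np.arange(4),
                               counts=np.zeros(4, dtype=int),
                               region=hg.SlabRegion(-10, -5))
        with pytest.raises(ValueError, match="spacing"):
            hg.summarize_occupancy(a, partner=b)


class TestDensityGrid:
    def test_uniform_bulk_normalizes_to_one(self):
        traj = hg.gen_uniform_water_trajectory(n_frames=150, seed=9,
                                               box=(20.0, 20.0, 20.0))
        grid = hg.water_density_grid(
            traj, hg.water_oxygens(traj.structure),
            hg.GridSpec(origin=np.zeros(3), shape=(40, 40, 40), spacing=0.5))
        assert grid.normalized.mean() == pytest.approx(1.0, abs=0.05)
        assert grid.overflow == 0

    def test_conservation_with_overflow(self, telegraph_run, caplog):
        _params, traj, _states, _series = telegraph_run
        water = hg.water_oxygens(traj.structure)
        # deliberately small grid: parked/reservoir waters overflow
        gspec = hg.GridSpec(origin=np.array([20.0, 20.0, 38.0]),
                            shape=(20, 20, 20), spacing=0.5)
        sub = hg.Trajectory(structure=traj.structure, times=traj.times[:200],
                            box=traj.box, moving_indices=traj.moving_indices,
                            moving_coords=traj.moving_coords[:200])
        with caplog.at_level(logging.WARNING, logger="hydrogate"):
            grid = hg.water_density_grid(sub, water, gspec)
        assert grid.total_deposits == 200 * len(water)
        assert grid.overflow > 0
        assert any("overflow" in r.message for r in caplog.records)

    def test_empty_region_is_all_zero(self):
        traj = hg.gen_uniform_water_trajectory(n_frames=5, seed=1,
                                               box=(10.0, 10.0, 10.0))
        gspec = hg.GridSpec(origin=np.array([100.0, 100.0, 100.0]),
                            shape=(4, 4, 4), spacing=0.5)
        grid = hg.water_density_grid(traj, hg.water_oxygens(traj.structure), gspec)
        assert np.all(grid.counts == 0)
        assert grid.overflow == grid.total_deposits

    def test_isosurface_voxel_report(self):
        grid = hg.DensityGrid(origin=np.zeros(3), spacing=1.0,
                              counts=np.array([[[0, 1], [2, 3]]]),
                              n_frames=2, bulk_density=1.0)
        # normalized = counts / 2 → values 0, .5, 1, 1.5
        assert grid.isosurface_voxel_count(0.5) == 3
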