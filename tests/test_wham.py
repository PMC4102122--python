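"""WHAM reconstruction, PMF conversion and profile comparison."""

import logging

import numpy as np
import pytest

import hydrogate as hg

KT = hg.KT_310K


def _reference_aligned_truth(pmf_profile, analytic):
    """Analytic G evaluated on the profile's bins, shifted to its reference."""
    ok = ~pmf_profile.mask
    g = analytic.evaluate(pmf_profile.z)
    ref_idx = np.flatnonzero(ok)[0] if pmf_profile.reference == "bulk_end" \
        else np.nanargmin(np.where(ok, pmf_profile.G, np.nan))
    return g - g[ref_idx], ok


class TestBiasEnergy:
    def test_quadratic_form(self):
        w = hg.UmbrellaWindow(center=-3.0, force_constant=10.0, kT=KT,
                              samples=np.array([0.0]))
        assert hg.bias_energy(w, -3.0) == 0.0
        assert hg.bias_energy(w, -2.0) == pytest.approx(5.0)   # ½·10·1²
        assert hg.bias_energy(w, -1.0) == pytest.approx(20.0)  # doubling Δz ×4


class TestWham:
    def test_unbiased_window_equals_boltzmann_inversion(self):
        """Single window, k=0: WHAM reduces to −kT·ln(histogram), which must
        track the analytic G with RMSE < 0.15 kT on well-sampled bins."""
        pmf = hg.AnalyticPMF("gaussian_barrier",
                             {"height": 2.0, "width": 2.0, "center": 0.0},
                             domain=(-6.0, 6.0))
        w = hg.gen_umbrella_samples(pmf, [0.0], k_bias=0.0, kT=KT,
                                    n_per_window=200_000, seed=3)[0]
        sol = hg.wham([w], bin_width=0.2)
        prof = hg.to_pmf(sol, reference="minimum")

        # independent oracle: direct normalized histogram inversion
        hist, edges = np.histogram(w.samples, bins=len(sol.bin_centers),
                                   range=(w.samples.min(),
                                          w.samples.min() + 0.2 * len(sol.bin_centers)))
        well_sampled = hist >= 100
        g_hist = -np.log(hist[well_sampled] / hist.sum())
        g_hist -= g_hist.min()
        g_wham = prof.G[well_sampled]
        assert np.sqrt(np.mean((g_wham - g_hist) ** 2)) < 1e-6

        truth, ok = _reference_aligned_truth(prof, pmf)
        good = ok & well_sampled
        rmse = np.sqrt(np.mean((prof.G[good] - truth[good]) ** 2))
        assert rmse < 0.15

    def test_flat_pmf_reconstructed_flat(self):
        pmf = hg.AnalyticPMF("flat", domain=(-10.0, 10.0))
        wins = hg.gen_umbrella_samples(pmf, np.arange(-9.0, 10.0, 1.0),
                                       k_bias=10.0, kT=KT,
                                       n_per_window=50_000, seed=5)
        prof = hg.to_pmf(hg.wham(wins))
        # flat within 0.1 kT across the window-covered span (outside the
        # outermost centers only the bias tails sample, so noise blows up)
        covered = (prof.z >= -9.0) & (prof.z <= 9.0)
        g = prof.G[covered]
        assert np.nanmax(g) - np.nanmin(g) < 2 * 0.1
        assert np.nanmax(np.abs(g - np.nanmean(g))) < 0.1

    @pytest.mark.parametrize("height", [3.0, 5.0])
    def test_barrier_recovery_25_window_protocol(self, height):
        """25 windows at 1-Å spacing, k = 10 kJ/mol/Å², 10⁴ samples/window:
        Gaussian barrier height recovered within 0.3 kT."""
        pmf = hg.AnalyticPMF("gaussian_barrier",
                             {"height": height, "width": 2.0, "center": -7.5},
                             domain=(-20.0, 4.0))
        centers = -20.0 + np.arange(25.0)
        wins = hg.gen_umbrella_samples(pmf, centers, k_bias=10.0, kT=KT,
                                       n_per_window=10_000, seed=int(height))
        sol = hg.wham(wins)
        assert sol.converged
        prof = hg.to_pmf(sol)
        assert abs(prof.barrier_height - height) < 0.3

    @pytest.mark.parametrize("form,params", [
        ("harmonic", {"k": 0.15, "center": -8.0}),
        ("double_well", {"height": 4.0, "half_separation": 6.0, "center": -8.0}),
    ])
    def test_profile_rmse_across_pmf_forms(self, form, params):
        pmf = hg.AnalyticPMF(form, params, domain=(-20.0, 4.0))
        centers = -20.0 + np.arange(25.0)
        wins = hg.gen_umbrella_samples(pmf, centers, k_bias=10.0, kT=KT,
                                       n_per_window=10_000, seed=42)
        prof = hg.to_pmf(hg.wham(wins))
        truth, ok = _reference_aligned_truth(prof, pmf)
        assert np.sqrt(np.nanmean((prof.G[ok] - truth[ok]) ** 2)) < 0.3

    def test_window_order_invariance(self):
        pmf = hg.AnalyticPMF("gaussian_barrier",
                             {"height": 3.0, "width": 2.0, "center": 0.0},
                             domain=(-8.0, 8.0))
        wins = hg.gen_umbrella_samples(pmf, np.arange(-7.0, 8.0), k_bias=10.0,
                                       kT=KT, n_per_window=2000, seed=9)
        a = hg.wham(wins)
        b = hg.wham(wins[::-1])
        assert np.array_equal(a.probabilities, b.probabilities)
        assert np.array_equal(a.window_free_energies, b.window_free_energies)

    def test_probabilities_normalized_and_residual_decreasing(self):
        pmf = hg.AnalyticPMF("harmonic", {"k": 0.2, "center": 0.0},
                             domain=(-8.0, 8.0))
        wins = hg.gen_umbrella_samples(pmf, np.arange(-6.0, 7.0, 2.0),
                                       k_bias=5.0, kT=KT,
                                       n_per_window=5000, seed=2)
        sol = hg.wham(wins)
        assert sol.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(sol.probabilities >= 0)
        assert sol.window_free_energies[0] == 0.0  # gauge
        tail = sol.residual_history[-100:]
        assert np.all(np.diff(tail) <= 1e-15)

    def test_bin_width_refinement_stable(self):
        pmf = hg.AnalyticPMF("gaussian_barrier",
                             {"height": 5.0, "width": 2.0, "center": -7.5},
                             domain=(-20.0, 4.0))
        wins = hg.gen_umbrella_samples(pmf, -20.0 + np.arange(25.0),
                                       k_bias=10.0, kT=KT,
                                       n_per_window=10_000, seed=11)
        b_coarse = hg.to_pmf(hg.wham(wins, bin_width=0.2)).barrier_height
        b_fine = hg.to_pmf(hg.wham(wins, bin_width=0.1)).barrier_height
        assert abs(b_coarse - b_fine) < 0.1

    def test_interior_empty_bins_masked_with_warning(self, caplog):
        # bimodal samples with an unvisited interior stretch
        rng = np.random.default_rng(0)
        samples = np.concatenate([rng.normal(-3.0, 0.3, 5000),
                                  rng.normal(3.0, 0.3, 5000)])
        w = hg.UmbrellaWindow(center=0.0, force_constant=0.0, kT=KT,
                              samples=samples)
        with caplog.at_level(logging.WARNING, logger="hydrogate"):
            sol = hg.wham([w], bin_width=0.2)
        interior_gap = (sol.bin_centers > -1.0) & (sol.bin_centers < 1.0)
        assert np.all(sol.mask[interior_gap])
        assert np.all(sol.probabilities[interior_gap] == 0)
        assert any("masked" in r.message for r in caplog.records)

    def test_disjoint_windows_hard_error(self):
        rng = np.random.default_rng(1)
        w1 = hg.UmbrellaWindow(center=-5.0, force_constant=10.0, kT=KT,
                               samples=rng.normal(-5.0, 0.2, 1000))
        w2 = hg.UmbrellaWindow(center=5.0, force_constant=10.0, kT=KT,
                               samples=rng.normal(5.0, 0.2, 1000))
        with pytest.raises(ValueError, match="overlap"):
            hg.wham([w1, w2])

    def test_mixed_kt_rejected(self):
        w1 = hg.UmbrellaWindow(0.0, 10.0, KT, np.array([0.0, 0.1]))
        w2 = hg.UmbrellaWindow(0.5, 10.0, 2 * KT, np.array([0.4, 0.6]))
        with pytest.raises(ValueError, match="kT"):
            hg.wham([w1, w2])


class TestToPmf:
    def _solution(self, P, z=None):
        P = np.asarray(P, dtype=float)
        z = np.arange(len(P), dtype=float) if z is None else z
        return hg.WHAMSolution(bin_centers=z, probabilities=P / P.sum(),
                               window_free_energies=np.zeros(1), kT=KT,
                               bin_width=1.0, iterations=1, converged=True,
                               tolerance=1e-6)

    def test_uniform_distribution_gives_zero_profile(self):
        prof = hg.to_pmf(self._solution([0.25] * 4))
        assert np.allclose(prof.G, 0.0)

    def test_two_bin_closed_form(self):
        prof = hg.to_pmf(self._solution([0.7, 0.3]))
        assert prof.G[0] == pytest.approx(0.0)
        assert prof.G[1] == pytest.approx(np.log(7.0 / 3.0))

    def test_minimum_reference(self):
        prof = hg.to_pmf(self._solution([0.1, 0.6, 0.3]), )
        prof_min = hg.to_pmf(self._solution([0.1, 0.6, 0.3]), reference="minimum")
        assert np.nanmin(prof_min.G) == pytest.approx(0.0)
        # shapes agree up to a constant
        assert np.allclose(np.diff(prof.G), np.diff(prof_min.G))

    def test_window_free_energy_gauge_does_not_affect_pmf(self):
        sol = self._solution([0.2, 0.5, 0.3])
        prof_a = hg.to_pmf(sol)
        sol.window_free_energies = sol.window_free_energies + 37.0
        prof_b = hg.to_pmf(sol)
        assert np.array_equal(prof_a.G, prof_b.G)


def _flat_profile(z, value=0.0):
    G = np.full_like(z, value, dtype=float)
    return hg.PMFProfile(z=z, G=G, reference="bulk_end",
                         mask=np.zeros(len(z), dtype=bool))


class TestComparePmfs:
    def test_identical_profiles_give_zero(self):
        z = np.arange(-15.0, 5.0, 0.1)
        a = _flat_profile(z, 1.0)
        rec = hg.compare_pmfs(a, a)
        assert np.allclose(rec.delta_G, 0.0)
        assert rec.peak_delta == 0.0
        assert rec.positive_area == 0.0

    def test_uniform_offset_rectangle_area(self):
        """A 4-kT uniform excess over a 10-Å region: peak 4 kT, area 40 kT·Å."""
        z = np.arange(-15.0, 5.0, 0.1)
        b = _flat_profile(z)
        Ga = np.where((z >= -12.0) & (z < -2.0), 4.0, 0.0)
        a = hg.PMFProfile(z=z, G=Ga, reference="bulk_end",
                          mask=np.zeros(len(z), dtype=bool))
        rec = hg.compare_pmfs(a, b, region=(-12.0, -2.0))
        assert rec.peak_delta == pytest.approx(4.0)
        assert rec.positive_area == pytest.approx(40.0, abs=0.5)

    def test_swapping_systems_negates_delta(self):
        z = np.arange(-10.0, 5.0, 0.1)
        rng = np.random.default_rng(4)
        a = hg.PMFProfile(z=z, G=rng.uniform(0, 3, len(z)), reference="bulk_end",
                          mask=np.zeros(len(z), dtype=bool))
        b = hg.PMFProfile(z=z, G=rng.uniform(0, 3, len(z)), reference="bulk_end",
                          mask=np.zeros(len(z), dtype=bool))
        ab = hg.compare_pmfs(a, b)
        ba = hg.compare_pmfs(b, a)
        assert np.allclose(ab.delta_G, -ba.delta_G)

    def test_rebinning_by_interpolation(self):
        za = np.arange(-10.0, 5.0, 0.1)
        zb = np.arange(-10.0, 5.0, 0.25)
        a = _flat_profile(za, 2.0)
        b = hg.PMFProfile(z=zb, G=0.1 * (zb + 10.0), reference="bulk_end",
                          mask=np.zeros(len(zb), dtype=bool))
        rec = hg.compare_pmfs(a, b, region=(-9.0, 4.0))
        expected = 2.0 - 0.1 * (rec.z + 10.0)
        ok = np.isfinite(rec.delta_G)
        assert np.allclose(rec.delta_G[ok], expected[ok], atol=1e-9)

    def test_disjoint_domains_rejected(self):
        a = _flat_profile(np.arange(-10.0, -5.0, 0.1))
        b = _flat_profile(np.arange(5.0, 10.0, 0.1))
        with pytest.raises(ValueError, match="disjoint"):
            hg.compare_pmfs(a, b)


class TestWindowFiles:
    def test_round_trip(self, tmp_path):
        w = hg.UmbrellaWindow(center=-3.5, force_constant=10.0, kT=KT,
                              samples=np.linspace(-4.0, -3.0, 50))
        path = tmp_path / "w00.tsv"
        hg.write_window(w, path)
        w2 = hg.read_window(path)
        assert w2.center == w.center
        assert w2.force_constant == w.force_constant
        assert w2.kT == w.kT
        assert np.abs(w2.samples - w.samples).max() < 1e-7
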