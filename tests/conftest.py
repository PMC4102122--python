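"""Shared fixtures: synthetic pores, frames and selections.

Expensive objects (pore structures, annealed profiles, long telegraph
runs) are session-scoped so unit and acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import hydrogate as hg

REF_EXPR = "residue_id=117 or residue_id=225"
WALL_EXPR = "residue_name=WAL"


@pytest.fixture(scope="session")
def cylinder_spec() -> hg.PoreSpec:
    return hg.PoreSpec(axis_length=40.0,
                       radius_knots=((-20.0, 5.0), (20.0, 5.0)),
                       constriction_zone=(-10.0, -5.0))


@pytest.fixture(scope="session")
def hourglass_spec() -> hg.PoreSpec:
    # waist r=2 Å at z=0, r=5 Å at the ends, gentle slopes
    return hg.PoreSpec(axis_length=60.0,
                       radius_knots=((-30.0, 5.0), (0.0, 2.0), (30.0, 5.0)),
                       constriction_zone=(-10.0, -5.0))


@pytest.fixture(scope="session")
def cylinder_system(cylinder_spec):
    s = hg.gen_pore_structure(cylinder_spec, seed=101)
    frame = hg.Frame(time=0.0, coordinates=s.coordinates, box=s.box)
    ref = hg.select(s, REF_EXPR)
    wall = hg.select(s, WALL_EXPR)
    pf = hg.compute_pore_frame(frame, ref)
    return s, frame, wall, pf


@pytest.fixture(scope="session")
def hourglass_system(hourglass_spec):
    s = hg.gen_pore_structure(hourglass_spec, seed=202)
    frame = hg.Frame(time=0.0, coordinates=s.coordinates, box=s.box)
    ref = hg.select(s, REF_EXPR)
    wall = hg.select(s, WALL_EXPR)
    pf = hg.compute_pore_frame(frame, ref)
    return s, frame, wall, pf


@pytest.fixture(scope="session")
def hourglass_profile_sa(hourglass_system):
    s, frame, wall, pf = hourglass_system
    return hg.radius_profile(frame, s, wall, pf, (-12.0, 12.0), 1.0, seed=7)


@pytest.fixture(scope="session")
def hourglass_profile_grid(hourglass_system):
    s, frame, wall, pf = hourglass_system
    return hg.radius_profile_grid(frame, s, wall, pf, (-12.0, 12.0), 1.0)


@pytest.fixture(scope="session")
def telegraph_run():
    """Balanced-rate telegraph wetting run, 10^4 frames at 0.1 ns."""
    spec = hg.PoreSpec()
    params = hg.WettingParams(k_dry=1.0, k_wet=1.0, lambda_full=12.0,
                              frame_dt=0.1, n_frames=10_000, seed=5)
    traj, states = hg.gen_wetting_trajectory(spec, params)
    water = hg.water_oxygens(traj.structure)
    ref = hg.select(traj.structure, REF_EXPR)
    series = hg.occupancy_series(traj, water, ref, hg.SlabRegion(-10.0, -5.0))
    return params, traj, states, series


def dwell_se(durations: list[float]) -> float:
    """Standard error of a dwell-time mean from observed episodes."""
    d = np.asarray(durations, dtype=float)
    return float(np.std(d, ddof=1) / np.sqrt(len(d)))
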