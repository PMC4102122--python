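"""Synthetic pores, wetting trajectories and umbrella windows.

Every downstream stage (geometry, hydration, WHAM) is validated against
this module's analytically known ground truth:

* :func:`gen_pore_structure` — pseudo-atomic pore walls whose maximal
  inscribed probe radius equals a prescribed piecewise-linear profile;
* :func:`gen_wetting_trajectory` — water trajectories whose gate-slab
  occupancy follows a two-state (telegraph) Markov process with known
  rates, emulating the stochastic wet/dry switching seen in hydrophobic
  constrictions;
* :func:`gen_umbrella_samples` — exact i.i.d. draws from the biased
  Boltzmann density of a known 1D free-energy profile under a harmonic
  umbrella restraint.

All generators are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Structure, Trajectory

__all__ = [
    "PoreSpec",
    "WettingParams",
    "WettingStates",
    "AnalyticPMF",
    "BULK_WATER_DENSITY",
    "gen_pore_structure",
    "gen_wetting_trajectory",
    "gen_umbrella_samples",
    "gen_uniform_water_trajectory",
]

#: Bulk water number density at ambient conditions (molecules Å⁻³).
BULK_WATER_DENSITY = 0.0334


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class PoreSpec:
    """Geometry of a model pore with a hydrophobic constriction.

    The wall radius profile is piecewise linear through ``radius_knots``
    ((z, r) pairs, z strictly increasing, r > 0) and flat beyond the
    outermost knots.  Defaults model a TWIK-1-like inner pore: a 5-Å
    vestibule narrowing to a 2-Å constriction centred 7.5 Å below the
    z = 0 anchor, with gentle wall slopes (≤ 0.15) so the inscribed
    probe radius equals the wall profile to within a few hundredths of
    an Å.
    """

    axis_length: float = 60.0
    radius_knots: tuple[tuple[float, float], ...] = (
        (-30.0, 5.0), (-7.5, 2.0), (30.0, 5.0))
    wall_atom_spacing: float = 1.0
    wall_vdw_radius: float = 1.7
    constriction_zone: tuple[float, float] = (-10.0, -5.0)

    def __post_init__(self) -> None:
        if self.wall_atom_spacing <= 0:
            raise ValueError("wall_atom_spacing must be positive")
        if self.wall_vdw_radius <= 0:
            raise ValueError("wall_vdw_radius must be positive")
        zs = np.array([k[0] for k in self.radius_knots], dtype=float)
        rs = np.array([k[1] for k in self.radius_knots], dtype=float)
        if len(zs) < 1 or np.any(np.diff(zs) <= 0):
            raise ValueError("radius_knots must be strictly increasing in z")
        if np.any(rs <= 0):
            raise ValueError("wall radii must be positive everywhere")
        if self.constriction_zone[0] >= self.constriction_zone[1]:
            raise ValueError("constriction_zone must satisfy z_lo < z_hi")

    def radius_at(self, z) -> np.ndarray:
        """Wall (probe) radius at axial position(s) z, Å."""
        zs = [k[0] for k in self.radius_knots]
        rs = [k[1] for k in self.radius_knots]
        return np.interp(z, zs, rs)

    @property
    def z_extent(self) -> tuple[float, float]:
        return (-self.axis_length / 2.0, self.axis_length / 2.0)


@dataclass
class WettingParams:
    """Two-state (telegraph) wetting/dewetting process parameters.

    ``k_dry`` is the wet→dry switching rate and ``k_wet`` the dry→wet
    rate, both in events/ns; ``lambda_full`` the expected slab water
    count while wet.  Defaults encode the study conditions: 0.1-ns frame
    spacing, one 100-ns run (1000 frames), 12 waters in a hydrated gate
    and a stationary dry fraction of 0.6 (dry slightly more than half
    the time).
    """

    k_dry: float = 1.2
    k_wet: float = 0.8
    lambda_full: float = 12.0
    frame_dt: float = 0.1
    n_frames: int = 1000
    seed: int = 0
    initial_state: str = "stationary"  # "wet" | "dry" | "stationary"
    bulk_density: float = BULK_WATER_DENSITY

    def __post_init__(self) -> None:
        if self.k_dry < 0 or self.k_wet < 0:
            raise ValueError("rates must be non-negative")
        if self.lambda_full < 0:
            raise ValueError("lambda_full must be non-negative")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.initial_state not in {"wet", "dry", "stationary"}:
            raise ValueError("initial_state must be wet, dry or stationary")

    # -- analytic properties of the telegraph process -----------------------

    @property
    def rate_sum(self) -> float:
        return self.k_dry + self.k_wet

    @property
    def dry_fraction(self) -> float:
        """Stationary probability of the dry state, k_dry/(k_dry+k_wet)."""
        if self.rate_sum == 0:
            return float("nan")
        return self.k_dry / self.rate_sum

    def switch_probabilities(self) -> tuple[float, float]:
        """Per-frame (wet→dry, dry→wet) switch probabilities at frame_dt."""
        rho = self.rate_sum
        if rho == 0:
            return 0.0, 0.0
        decay = -np.expm1(-rho * self.frame_dt)
        return self.k_dry / rho * decay, self.k_wet / rho * decay

    def dwell_means_continuous(self) -> tuple[float, float]:
        """(wet, dry) mean dwell times of the continuous process, ns."""
        wet = np.inf if self.k_dry == 0 else 1.0 / self.k_dry
        dry = np.inf if self.k_wet == 0 else 1.0 / self.k_wet
        return wet, dry

    def dwell_means_sampled(self) -> tuple[float, float]:
        """(wet, dry) mean dwell times as seen at frame_dt sampling, ns.

        Sampling at a finite stride makes episode lengths geometric in
        frames; the exact means are frame_dt / switch probability, which
        exceed the continuous 1/k by O(rate·dt) discretisation bias.
        """
        p_wd, p_dw = self.switch_probabilities()
        wet = np.inf if p_wd == 0 else self.frame_dt / p_wd
        dry = np.inf if p_dw == 0 else self.frame_dt / p_dw
        return wet, dry

    def dry_fraction_se(self, n_frames: int | None = None) -> float:
        """Std. error of the empirical dry fraction over n_frames.

        Accounts for the frame-to-frame autocorrelation of the sampled
        telegraph state, φ = exp(−(k_dry+k_wet)·frame_dt).
        """
        n = self.n_frames if n_frames is None else n_frames
        p = self.dry_fraction
        phi = np.exp(-self.rate_sum * self.frame_dt)
        return float(np.sqrt(p * (1 - p) / n * (1 + phi) / (1 - phi)))


@dataclass
class WettingStates:
    """Hidden wet/dry state sequence of a generated trajectory."""

    times: np.ndarray
    wet: np.ndarray  # bool per frame
    params: WettingParams

    @property
    def dry_fraction(self) -> float:
        return float(np.mean(~self.wet))


@dataclass
class AnalyticPMF:
    """Closed-form 1D free-energy profile G(z), in kT units.

    Forms (``params`` keys):
      * ``flat``: none — G ≡ 0;
      * ``harmonic``: ``k`` (kT/Å²), ``center`` (Å);
      * ``gaussian_barrier``: ``height`` (kT), ``width`` (Å, Gaussian σ),
        ``center`` (Å);
      * ``double_well``: ``height`` (kT, barrier), ``half_separation``
        (Å), ``center`` (Å) — G = height·(((z−c)/a)² − 1)².
    """

    form: str
    params: dict = field(default_factory=dict)
    domain: tuple[float, float] = (-20.0, 5.0)

    def __post_init__(self) -> None:
        if self.form not in {"flat", "harmonic", "gaussian_barrier", "double_well"}:
            raise ValueError(f"unknown PMF form {self.form!r}")
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("domain must be a finite (z_min, z_max) with z_min < z_max")
        if not np.all(np.isfinite(self.evaluate(np.linspace(lo, hi, 101)))):
            raise ValueError("PMF must be finite on its domain")

    def evaluate(self, z) -> np.ndarray:
        """G(z) in kT."""
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "harmonic":
            return 0.5 * p["k"] * (z - p["center"]) ** 2
        if self.form == "gaussian_barrier":
            return p["height"] * np.exp(-((z - p["center"]) ** 2)
                                        / (2.0 * p["width"] ** 2))
        u = (z - p["center"]) / p["half_separation"]
        return p["height"] * (u ** 2 - 1.0) ** 2

    @property
    def barrier_height(self) -> float:
        """max G − min G over the domain (kT), on a fine grid."""
        g = self.evaluate(np.linspace(*self.domain, 5001))
        return float(np.max(g) - np.min(g))


# ---------------------------------------------------------------------------
# Pore structure generator
# ---------------------------------------------------------------------------

def gen_pore_structure(spec: PoreSpec, seed: int = 0,
                       origin: Sequence[float] = (25.0, 25.0, 50.0),
                       box: Sequence[float] = (50.0, 50.0, 120.0)) -> Structure:
    """Build a pseudo-atomic pore wall realising ``spec``'s radius profile.

    Wall atoms sit on rings of radius ``radius_at(z) + wall_vdw_radius``
    at z steps of ``wall_atom_spacing`` (ring phase randomised per ring,
    deterministic for the seed), so the maximal inscribed probe radius
    at z equals ``radius_at(z)`` for gently sloped walls.  Two reference
    pseudo-atoms (the S4-site stand-ins, residues 117 and 225 on chains
    A and B) are embedded in the wall ring at z = 0 so their centroid
    lies on the axis at z = 0.
    """
    rng = np.random.default_rng(seed)
    origin = np.asarray(origin, dtype=float)
    lo, hi = spec.z_extent
    ring_z = np.arange(lo, hi + 1e-9, spec.wall_atom_spacing)

    xyz, ring_ids = [], []
    for i, z in enumerate(ring_z):
        ring_r = float(spec.radius_at(z)) + spec.wall_vdw_radius
        n_at = max(3, int(np.ceil(2 * np.pi * ring_r / spec.wall_atom_spacing)))
        theta = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.arange(n_at) / n_at
        ring = np.column_stack([ring_r * np.cos(theta), ring_r * np.sin(theta),
                                np.full(n_at, z)])
        xyz.append(ring)
        ring_ids.extend([i + 1] * n_at)
    wall = np.concatenate(xyz)
    n_wall = len(wall)

    ref_r = float(spec.radius_at(0.0)) + spec.wall_vdw_radius
    refs = np.array([[ref_r, 0.0, 0.0], [-ref_r, 0.0, 0.0]])

    coords = np.vstack([wall, refs]) + origin
    n = n_wall + 2
    names = np.array(["W"] * n_wall + ["REF", "REF"], dtype=object)
    resnames = np.array(["WAL"] * n_wall + ["THR", "THR"], dtype=object)
    resids = np.array(ring_ids + [117, 225], dtype=int)
    chains = np.array(["A"] * n_wall + ["A", "B"], dtype=object)
    elements = np.array(["C"] * n_wall + ["O", "O"], dtype=object)
    vdw = np.array([spec.wall_vdw_radius] * n_wall + [1.52, 1.52])
    return Structure(names=names, residue_names=resnames, residue_ids=resids,
                     chains=chains, elements=elements, vdw_radii=vdw,
                     coordinates=coords, box=np.asarray(box, dtype=float))


# ---------------------------------------------------------------------------
# Wetting/dewetting trajectory generator
# ---------------------------------------------------------------------------

def _telegraph_states(params: WettingParams, rng: np.random.Generator) -> np.ndarray:
    """Sampled wet(True)/dry(False) sequence of the telegraph process."""
    p_wd, p_dw = params.switch_probabilities()
    if params.initial_state == "wet":
        wet = True
    elif params.initial_state == "dry":
        wet = False
    else:  # stationary (absorbing state if one rate is zero)
        if params.rate_sum == 0:
            wet = True
        else:
            wet = rng.random() >= params.dry_fraction
    u = rng.random(params.n_frames)
    out = np.empty(params.n_frames, dtype=bool)
    for i in range(params.n_frames):
        out[i] = wet
        if wet:
            if u[i] < p_wd:
                wet = False
        elif u[i] < p_dw:
            wet = True
    return out


def _sample_in_profile(spec: PoreSpec, z_lo: float, z_hi: float, n: int,
                       rng: np.random.Generator,
                       radius_override: float | None = None) -> np.ndarray:
    """Uniform points inside the pore volume between z_lo and z_hi."""
    zg = np.linspace(z_lo, z_hi, max(int((z_hi - z_lo) / 0.01), 2))
    r = np.full_like(zg, radius_override) if radius_override is not None \
        else spec.radius_at(zg)
    w = r ** 2
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(zg))])
    cdf /= cdf[-1]
    z = np.interp(rng.random(n), cdf, zg)
    rad = np.interp(z, zg, r) * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([rad * np.cos(theta), rad * np.sin(theta), z])


def _pore_volume(spec: PoreSpec, z_lo: float, z_hi: float) -> float:
    zg = np.linspace(z_lo, z_hi, max(int((z_hi - z_lo) / 0.01), 2))
    return float(np.trapezoid(np.pi * spec.radius_at(zg) ** 2, zg))


def gen_wetting_trajectory(spec: PoreSpec, params: WettingParams,
                           origin: Sequence[float] = (25.0, 25.0, 50.0),
                           box: Sequence[float] = (50.0, 50.0, 120.0),
                           reservoir_depth: float = 10.0,
                           ) -> tuple[Trajectory, WettingStates]:
    """Simulate telegraph wetting/dewetting of the constriction slab.

    Wet frames hold Poisson(``lambda_full``) water oxygens placed
    uniformly in the constriction-zone volume; dry frames hold none.  A
    constant-count water background at ``bulk_density`` fills the rest
    of the pore plus a cytoplasmic reservoir below it (ideal-gas water:
    positions redrawn each frame).  The water pool has fixed size, so
    every frame has the same atom count; slab waters not in use are
    parked far below the reservoir, outside every analysis region.

    Returns the trajectory and the hidden state series.
    """
    rng = np.random.default_rng(params.seed)
    origin = np.asarray(origin, dtype=float)
    z_pore_lo, z_pore_hi = spec.z_extent
    z_slab_lo, z_slab_hi = spec.constriction_zone

    base = gen_pore_structure(spec, seed=params.seed, origin=origin, box=box)
    n_base = base.n_atoms

    # fixed-size water pool
    n_slab_pool = int(np.ceil(params.lambda_full + 6 * np.sqrt(params.lambda_full) + 1))
    v_below = _pore_volume(spec, z_pore_lo, z_slab_lo)
    v_above = _pore_volume(spec, z_slab_hi, z_pore_hi)
    r_res = float(spec.radius_at(z_pore_lo))
    v_res = np.pi * r_res ** 2 * reservoir_depth
    n_bg = int(round(params.bulk_density * (v_below + v_above + v_res)))
    n_w = n_slab_pool + n_bg

    names = np.concatenate([base.names, np.array(["OW"] * n_w, dtype=object)])
    resnames = np.concatenate([base.residue_names, np.array(["SOL"] * n_w, dtype=object)])
    resids = np.concatenate([base.residue_ids, 1000 + np.arange(n_w)])
    chains = np.concatenate([base.chains, np.array(["W"] * n_w, dtype=object)])
    elements = np.concatenate([base.elements, np.array(["O"] * n_w, dtype=object)])
    vdw = np.concatenate([base.vdw_radii, np.full(n_w, 1.52)])
    park = origin + np.array([0.0, 0.0, z_pore_lo - reservoir_depth - 20.0])
    coords0 = np.vstack([base.coordinates,
                         park + np.column_stack([0.1 * np.arange(n_w),
                                                 np.zeros(n_w), np.zeros(n_w)])])
    structure = Structure(names=names, residue_names=resnames, residue_ids=resids,
                          chains=chains, elements=elements, vdw_radii=vdw,
                          coordinates=coords0, box=np.asarray(box, dtype=float))

    F = params.n_frames
    times = params.frame_dt * np.arange(F)
    wet = _telegraph_states(params, rng)
    n_slab = np.where(wet, rng.poisson(params.lambda_full, size=F), 0)
    n_slab = np.minimum(n_slab, n_slab_pool)

    moving = np.empty((F, n_w, 3))
    # parked defaults for the slab pool
    moving[:, :n_slab_pool, :] = (coords0[n_base:n_base + n_slab_pool] - origin)
    total_slab = int(n_slab.sum())
    slab_pts = _sample_in_profile(spec, z_slab_lo, z_slab_hi, total_slab, rng) \
        if total_slab else np.empty((0, 3))
    offsets = np.concatenate([[0], np.cumsum(n_slab)])
    for f in range(F):
        k = n_slab[f]
        if k:
            moving[f, :k, :] = slab_pts[offsets[f]:offsets[f + 1]]

    # background: split counts by sub-region volume (fixed split, uniform inside)
    v_tot = v_below + v_above + v_res
    n_below = int(round(n_bg * v_below / v_tot))
    n_above = int(round(n_bg * v_above / v_tot))
    n_res = n_bg - n_below - n_above
    col = n_slab_pool
    for count, (zl, zh, r_ov) in (
        (n_below, (z_pore_lo, z_slab_lo, None)),
        (n_above, (z_slab_hi, z_pore_hi, None)),
        (n_res, (z_pore_lo - reservoir_depth, z_pore_lo, r_res)),
    ):
        if count:
            pts = _sample_in_profile(spec, zl, zh, F * count, rng,
                                     radius_override=r_ov)
            moving[:, col:col + count, :] = pts.reshape(F, count, 3)
        col += count

    moving += origin  # pore frame → lab frame (axis = lab z)
    traj = Trajectory(structure=structure, times=times,
                      box=np.asarray(box, dtype=float),
                      moving_indices=np.arange(n_base, n_base + n_w),
                      moving_coords=moving)
    return traj, WettingStates(times=times, wet=wet, params=params)


def gen_uniform_water_trajectory(n_frames: int = 100, seed: int = 0,
                                 box: Sequence[float] = (20.0, 20.0, 20.0),
                                 density: float = BULK_WATER_DENSITY) -> Trajectory:
    """Ideal-gas water box at the given density (bulk-water fixture).

    The molecule count is the rounded expectation (constant across
    frames); positions are redrawn uniformly each frame.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    n_w = int(round(density * np.prod(box)))
    structure = Structure(
        names=np.array(["OW"] * n_w, dtype=object),
        residue_names=np.array(["SOL"] * n_w, dtype=object),
        residue_ids=1 + np.arange(n_w),
        chains=np.array(["W"] * n_w, dtype=object),
        elements=np.array(["O"] * n_w, dtype=object),
        vdw_radii=np.full(n_w, 1.52),
        coordinates=np.zeros((n_w, 3)),
        box=box,
    )
    moving = rng.random((n_frames, n_w, 3)) * box
    return Trajectory(structure=structure, times=0.1 * np.arange(n_frames),
                      box=box, moving_indices=np.arange(n_w),
                      moving_coords=moving)


# ---------------------------------------------------------------------------
# Umbrella-window sampler
# ---------------------------------------------------------------------------

def gen_umbrella_samples(pmf: AnalyticPMF, centers: Sequence[float],
                         k_bias: float, kT: float,
                         n_per_window: int = 62500, seed: int = 0,
                         grid_step: float = 0.01,
                         ar1_phi: float = 0.0) -> list:
    """Exact draws from the biased densities of an analytic PMF.

    For each window centre z_i, samples z i.i.d. from
    p_i(z) ∝ exp(−(G(z) + ½·k_bias·(z−z_i)²)/kT) by inverse-CDF lookup
    on a grid of step ≤ ``grid_step``; G is converted from kT units to
    kJ/mol with the given kT.  ``ar1_phi`` > 0 imposes a Gaussian-copula
    AR(1) correlation on the uniform driver to emulate MD
    autocorrelation (marginals stay exact).  Deterministic per seed.
    """
    from .wham import UmbrellaWindow

    if kT <= 0:
        raise ValueError("kT must be positive")
    if k_bias < 0:
        raise ValueError("k_bias must be non-negative")
    if n_per_window <= 0:
        raise ValueError("n_per_window must be positive")
    if not (0.0 <= ar1_phi < 1.0):
        raise ValueError("ar1_phi must be in [0, 1)")
    lo, hi = pmf.domain
    centers = np.asarray(centers, dtype=float)
    if np.any(centers < lo) or np.any(centers > hi):
        raise ValueError("all window centers must lie inside the PMF domain")

    n_grid = max(int(np.ceil((hi - lo) / grid_step)) + 1, 2)
    zg = np.linspace(lo, hi, n_grid)
    g_kj = pmf.evaluate(zg) * kT
    windows = []
    for i, c in enumerate(centers):
        rng = np.random.default_rng([seed, i])
        u_tot = g_kj + 0.5 * k_bias * (zg - c) ** 2
        logw = -(u_tot - u_tot.min()) / kT
        w = np.exp(logw)
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
        if cdf[-1] <= 0:
            raise ValueError(f"window {i}: biased density is not normalizable")
        cdf /= cdf[-1]
        if ar1_phi > 0.0:
            from scipy.stats import norm
            e = np.empty(n_per_window)
            e[0] = rng.normal()
            innov = rng.normal(size=n_per_window) * np.sqrt(1 - ar1_phi ** 2)
            for t in range(1, n_per_window):
                e[t] = ar1_phi * e[t - 1] + innov[t]
            u = norm.cdf(e)
        else:
            u = rng.random(n_per_window)
        samples = np.interp(u, cdf, zg)
        windows.append(UmbrellaWindow(center=float(c), force_constant=float(k_bias),
                                      kT=float(kT), samples=samples))
    return windows
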