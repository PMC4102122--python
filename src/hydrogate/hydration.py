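"""Wetting/dewetting quantification: slab occupancy and density maps.

The gate region is a z slab in the pore frame (default −10 Å to −5 Å,
the stretch below the S4 reference where hydrophobic constrictions
dewet).  Per-frame water-oxygen counts n_H2O(t) yield occupancy series,
normalized histograms, the mean occupancy μ (and Δμ between systems),
and dry/wet dwell-time statistics.  Time-averaged 3D water-oxygen
densities are reported normalized to bulk water (1 = bulk), so the
conventional 0.5 isovalue marks half-bulk density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import AtomSelection, Frame
from .geometry import PoreFrame, compute_pore_frame

logger = logging.getLogger("hydrogate")

__all__ = [
    "SlabRegion",
    "OccupancySeries",
    "OccupancyHistogram",
    "DwellEpisode",
    "OccupancySummary",
    "GridSpec",
    "DensityGrid",
    "count_waters_in_slab",
    "occupancy_series",
    "occupancy_histogram",
    "summarize_occupancy",
    "water_density_grid",
]

BULK_WATER_DENSITY = 0.0334  # molecules Å⁻³


@dataclass
class SlabRegion:
    """Axial slab [z_lo, z_hi) in the pore frame, optional radial cap.

    The half-open upper bound lets adjacent slabs tile without double
    counting.  ``radial_cutoff`` (Å, strict <) restricts to a cylinder
    around the pore axis; None (default) counts by z only.
    """

    z_lo: float = -10.0
    z_hi: float = -5.0
    radial_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.z_lo >= self.z_hi:
            raise ValueError("slab requires z_lo < z_hi")
        if self.radial_cutoff is not None and self.radial_cutoff <= 0:
            raise ValueError("radial_cutoff must be positive or None")


@dataclass
class OccupancySeries:
    times: np.ndarray   # ns
    counts: np.ndarray  # integer n_H2O per frame
    region: SlabRegion

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def frame_dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self) > 1 else np.nan


@dataclass
class OccupancyHistogram:
    count_values: np.ndarray
    probabilities: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def probability_of(self, count: int) -> float:
        idx = np.flatnonzero(self.count_values == count)
        return float(self.probabilities[idx[0]]) if len(idx) else 0.0


@dataclass
class DwellEpisode:
    state: str            # "dry" | "wet"
    duration: float       # ns
    n_frames: int
    censored: bool        # touches the start or end of the series


@dataclass
class OccupancySummary:
    mu: float
    fraction_zero: float
    dwell_episodes: list[DwellEpisode]
    n_frames: int
    frame_dt: float
    delta_mu: float | None = None

    def mean_dwell(self, state: str, include_censored: bool = False) -> float:
        """Mean dwell time (ns) over episodes of one state."""
        eps = [e.duration for e in self.dwell_episodes
               if e.state == state and (include_censored or not e.censored)]
        return float(np.mean(eps)) if eps else np.nan

    def n_episodes(self, state: str, include_censored: bool = False) -> int:
        return sum(1 for e in self.dwell_episodes
                   if e.state == state and (include_censored or not e.censored))


def count_waters_in_slab(frame: Frame, water_oxygens: AtomSelection,
                         pore_frame: PoreFrame, region: SlabRegion,
                         empty_ok: bool = False) -> int:
    """Number of selected oxygens with z in [z_lo, z_hi).

    With a radial cutoff, additionally requires in-plane distance from
    the axis < cutoff.
    """
    if len(water_oxygens) == 0:
        if empty_ok:
            return 0
        raise ValueError("water selection is empty (pass empty_ok=True to allow)")
    pos = frame.coordinates[water_oxygens.indices]
    z = pore_frame.z_of(pos)
    mask = (z >= region.z_lo) & (z < region.z_hi)
    if region.radial_cutoff is not None and mask.any():
        rel = pos[mask] - pore_frame.origin
        perp = rel - np.outer(rel @ pore_frame.axis, pore_frame.axis)
        mask_r = np.linalg.norm(perp, axis=1) < region.radial_cutoff
        return int(np.count_nonzero(mask_r))
    return int(np.count_nonzero(mask))


def occupancy_series(trajectory: Iterable[Frame], water_oxygens: AtomSelection,
                     ref_sel: AtomSelection, region: SlabRegion,
                     stride: int = 1, axis_mode: str = "fixed_z",
                     axis_sel: AtomSelection | None = None) -> OccupancySeries:
    """Per-frame slab water counts, recomputing the pore frame each frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    times, counts = [], []
    for i, frame in enumerate(trajectory):
        if i % stride:
            continue
        pf = compute_pore_frame(frame, ref_sel, axis_mode=axis_mode,
                                axis_sel=axis_sel)
        times.append(frame.time)
        counts.append(count_waters_in_slab(frame, water_oxygens, pf, region))
    if not counts:
        raise ValueError("trajectory yielded no frames")
    return OccupancySeries(times=np.array(times), counts=np.array(counts),
                           region=region)


def occupancy_histogram(series: OccupancySeries | Sequence[OccupancySeries]
                        ) -> OccupancyHistogram:
    """Normalized distribution of integer water counts.

    Accepts one series or several (e.g. repeat runs), pooled by
    concatenation.
    """
    if isinstance(series, OccupancySeries):
        series = [series]
    if not series:
        raise ValueError("no occupancy series given")
    counts = np.concatenate([s.counts for s in series])
    if counts.size == 0:
        raise ValueError("occupancy series are empty")
    values = np.arange(counts.max() + 1)
    freq = np.bincount(counts, minlength=len(values)).astype(float)
    return OccupancyHistogram(count_values=values, probabilities=freq / freq.sum(),
                              n_frames=int(counts.size))


def _episodes(counts: np.ndarray, dt: float) -> list[DwellEpisode]:
    dry = counts == 0
    episodes: list[DwellEpisode] = []
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or dry[i] != dry[start]:
            n = i - start
            episodes.append(DwellEpisode(
                state="dry" if dry[start] else "wet",
                duration=n * dt, n_frames=n,
                censored=(start == 0 or i == len(counts)),
            ))
            start = i
    return episodes


def summarize_occupancy(series: OccupancySeries,
                        partner: OccupancySeries | None = None) -> OccupancySummary:
    """Mean occupancy μ, dry fraction, dwell episodes, optional Δμ.

    Dwell episodes are maximal runs of zero (dry) or nonzero (wet)
    counts, converted to ns with the frame spacing; boundary episodes
    are kept but flagged censored.  With a partner series,
    ``delta_mu = μ(series) − μ(partner)`` (call with the mutant first to
    report the conventional mutant-minus-WT Δμ).
    """
    if len(series) == 0:
        raise ValueError("occupancy series is empty")
    dt = series.frame_dt
    if partner is not None:
        dt_p = partner.frame_dt
        if np.isfinite(dt) and np.isfinite(dt_p) and abs(dt - dt_p) > 1e-9:
            raise ValueError(
                f"frame spacing mismatch: {dt} ns vs partner {dt_p} ns")
    mu = float(np.mean(series.counts))
    frac0 = float(np.mean(series.counts == 0))
    eps = _episodes(series.counts, dt if np.isfinite(dt) else 0.0)
    delta = None if partner is None else mu - float(np.mean(partner.counts))
    return OccupancySummary(mu=mu, fraction_zero=frac0, dwell_episodes=eps,
                            n_frames=len(series), frame_dt=dt, delta_mu=delta)


# ---------------------------------------------------------------------------
# 3D density grids
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Regular cubic-voxel grid: lower corner, voxel counts, spacing (Å)."""

    origin: np.ndarray
    shape: tuple[int, int, int]
    spacing: float = 0.5

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(s) for s in self.shape)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(s <= 0 for s in self.shape):
            raise ValueError("grid shape must be positive")

    @classmethod
    def covering(cls, lower: Sequence[float], upper: Sequence[float],
                 spacing: float = 0.5) -> "GridSpec":
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        shape = tuple(int(np.ceil((u - l) / spacing)) for l, u in zip(lower, upper))
        return cls(origin=lower, shape=shape, spacing=spacing)


@dataclass
class DensityGrid:
    """Time-averaged water-oxygen density, normalized to bulk.

    ``counts`` holds total deposits per voxel over all frames;
    ``normalized = counts / (n_frames · voxel_volume · bulk_density)``
    is dimensionless with 1 = bulk water.  Deposits falling outside the
    grid are tallied in ``overflow`` (conservation:
    counts.sum() + overflow = total deposits).
    """

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_frames: int
    bulk_density: float = BULK_WATER_DENSITY
    overflow: int = 0

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing ** 3)

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts / self.n_frames

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / (self.n_frames * self.voxel_volume * self.bulk_density)

    @property
    def total_deposits(self) -> int:
        return int(self.counts.sum()) + int(self.overflow)

    def isosurface_voxel_count(self, isovalue: float = 0.5) -> int:
        """Number of voxels at or above the isovalue (default half bulk)."""
        return int(np.count_nonzero(self.normalized >= isovalue))


def water_density_grid(trajectory: Iterable[Frame], water_oxygens: AtomSelection,
                       grid_spec: GridSpec,
                       bulk_density: float = BULK_WATER_DENSITY) -> DensityGrid:
    """Accumulate per-frame water-oxygen deposits on a regular grid.

    Nearest-voxel binning: each oxygen deposits 1 into the voxel cell
    containing it.  Oxygens outside the grid go to the overflow tally
    with a warning (never silently dropped).
    """
    if len(water_oxygens) == 0:
        raise ValueError("water selection is empty")
    counts = np.zeros(grid_spec.shape, dtype=np.int64)
    overflow = 0
    n_frames = 0
    shape = np.array(grid_spec.shape)
    for frame in trajectory:
        n_frames += 1
        pos = frame.coordinates[water_oxygens.indices]
        idx = np.floor((pos - grid_spec.origin) / grid_spec.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        overflow += int(np.count_nonzero(~ok))
        good = idx[ok]
        np.add.at(counts, (good[:, 0], good[:, 1], good[:, 2]), 1)
    if n_frames == 0:
        raise ValueError("trajectory yielded no frames")
    if overflow:
        logger.warning("water_density_grid: %d deposit(s) fell outside the grid "
                       "(tallied as overflow)", overflow)
    return DensityGrid(origin=grid_spec.origin.copy(), spacing=grid_spec.spacing,
                       counts=counts, n_frames=n_frames,
                       bulk_density=bulk_density, overflow=overflow)
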