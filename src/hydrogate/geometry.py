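"""Pore-aligned coordinate frame and maximal-sphere radius profiles.

The pore frame puts z = 0 at the reference site (for TWIK-1, the
centroid of the Thr117/Thr225 residues at the S4 ion binding site) with
the cytoplasmic vestibule at negative z.  The radius profile is the
classic maximal-inscribed-sphere measure: at each z slice, the radius
of the largest probe sphere centred in that plane that touches no
atom's van der Waals sphere,

    r(z) = max_{p : p_z = z}  min_i ( |p - x_i| - vdw_i ),

maximised over the in-plane position p by simulated annealing.  The
sphere test uses true 3D distances; the slice only constrains the probe
centre.  This assumes a near-axial pore (no curved pathfinding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import AtomSelection, Frame, Structure

logger = logging.getLogger("hydrogate")

__all__ = [
    "PoreFrame",
    "RadiusProfile",
    "AnnealParams",
    "compute_pore_frame",
    "radius_profile",
    "radius_profile_grid",
    "classify_profile",
]


@dataclass
class PoreFrame:
    """Affine frame of the pore: origin (z = 0 anchor) and axis unit vector."""

    origin: np.ndarray
    axis: np.ndarray
    per_frame: bool = True

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if not np.isfinite(self.origin).all():
            raise ValueError("pore-frame origin must be finite")
        if norm == 0:
            raise ValueError("pore axis must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            self.axis = self.axis / norm

    def z_of(self, points: np.ndarray) -> np.ndarray:
        """Axial coordinate(s) of lab-frame point(s): dot(p − origin, axis)."""
        return np.atleast_2d(np.asarray(points, dtype=float) - self.origin) @ self.axis

    def in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors orthogonal to the axis (and to each other)."""
        seed = np.array([1.0, 0.0, 0.0])
        if abs(self.axis @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - (seed @ self.axis) * self.axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.axis, e1)
        return e1, e2


@dataclass
class RadiusProfile:
    z_values: np.ndarray
    radii: np.ndarray
    classification: np.ndarray | None = None
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.z_values) != len(self.radii):
            raise ValueError("z_values and radii must have equal length")
        dz = np.diff(self.z_values)
        if len(dz) and (np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-9)):
            raise ValueError("z_values must strictly increase with constant step")

    @property
    def min_radius(self) -> float:
        return float(np.min(self.radii))

    @property
    def z_at_min(self) -> float:
        return float(self.z_values[int(np.argmin(self.radii))])


@dataclass
class AnnealParams:
    """Simulated-annealing schedule for the in-plane probe search."""

    n_proposals: int = 2000
    initial_step: float = 0.5        # Å, in-plane proposal scale
    decay: float = 0.9               # step (and temperature) multiplier
    decay_every: int = 100           # proposals between decays
    initial_temperature: float = 0.2  # Å, Metropolis scale for downhill moves
    z_cutoff: float = 8.0            # Å, atoms beyond |dz| ignored in a slice


def compute_pore_frame(frame: Frame, ref_sel: AtomSelection,
                       axis_mode: str = "fixed_z",
                       axis_sel: AtomSelection | None = None) -> PoreFrame:
    """Anchor the pore frame: origin at the reference-selection centroid.

    ``axis_mode='fixed_z'`` uses the lab z axis; ``'principal'`` uses the
    dominant principal axis of ``axis_sel`` (a pore-lining selection),
    oriented toward +z.  Points below the anchor (cytoplasmic side) get
    negative z.
    """
    if len(ref_sel) == 0:
        raise ValueError("reference selection is empty")
    origin = frame.coordinates[ref_sel.indices].mean(axis=0)
    if axis_mode == "fixed_z":
        axis = np.array([0.0, 0.0, 1.0])
    elif axis_mode == "principal":
        if axis_sel is None or len(axis_sel) < 3:
            raise ValueError("axis_mode='principal' needs an axis selection of >=3 atoms")
        pts = frame.coordinates[axis_sel.indices]
        cov = np.cov((pts - pts.mean(axis=0)).T)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] < 1e-12 or (evals[-1] - evals[-2]) / max(evals[-1], 1e-300) < 1e-6:
            raise ValueError("degenerate principal axis: selection is isotropic")
        axis = evecs[:, -1]
        if axis[2] < 0:
            axis = -axis
    else:
        raise ValueError(f"unknown axis_mode {axis_mode!r}")
    return PoreFrame(origin=origin, axis=axis)


def _pore_coords(frame: Frame, structure: Structure, atoms: AtomSelection,
                 pore_frame: PoreFrame) -> tuple[np.ndarray, np.ndarray]:
    """Selected atom coordinates in the pore frame, plus their vdW radii."""
    e1, e2 = pore_frame.in_plane_basis()
    basis = np.stack([e1, e2, pore_frame.axis], axis=1)
    coords = (frame.coordinates[atoms.indices] - pore_frame.origin) @ basis
    vdw = np.asarray(structure.vdw_radii, dtype=float)[atoms.indices]
    return coords, vdw


def _clearance(xy: np.ndarray, atom_xy: np.ndarray, atom_dz2: np.ndarray,
               atom_vdw: np.ndarray) -> np.ndarray:
    """min_i (3D distance − vdw_i) for probe centres ``xy`` of shape (m, 2)."""
    diff = xy[:, None, :] - atom_xy[None, :, :]
    d = np.sqrt(np.einsum("mij,mij->mi", diff, diff) + atom_dz2[None, :])
    return np.min(d - atom_vdw[None, :], axis=1)


def radius_profile(frame: Frame, structure: Structure, atoms: AtomSelection,
                   pore_frame: PoreFrame, z_range: tuple[float, float],
                   z_step: float, search: AnnealParams | None = None,
                   seed: int = 0) -> RadiusProfile:
    """Maximal-sphere radius at each z slice via seeded simulated annealing.

    Slices run from ``z_range[0]`` to ``z_range[1]`` (inclusive, uniform
    ``z_step``); each slice's search starts at the previous slice's
    optimum (the first starts on the axis).  Uphill moves are always
    accepted; downhill moves with Metropolis probability under a
    temperature annealed on the same schedule as the step size.
    Deterministic for a fixed seed; radii are clipped at 0.  A slice
    with no atom inside the z cutoff reports +inf with a warning.
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    if len(atoms) == 0:
        raise ValueError("atom selection is empty")
    p = search or AnnealParams()
    rng = np.random.default_rng(seed)
    coords, vdw = _pore_coords(frame, structure, atoms, pore_frame)

    n_slices = int(round((z_range[1] - z_range[0]) / z_step)) + 1
    z_values = z_range[0] + z_step * np.arange(n_slices)
    radii = np.empty(n_slices)
    best_xy = np.zeros(2)  # warm start: on the axis
    for si, z in enumerate(z_values):
        dz = coords[:, 2] - z
        mask = np.abs(dz) <= p.z_cutoff
        if not mask.any():
            logger.warning("radius_profile: no atoms within %.1f Å of slice z=%.2f",
                           p.z_cutoff, z)
            radii[si] = np.inf
            continue
        axy, adz2, avdw = coords[mask, :2], dz[mask] ** 2, vdw[mask]
        cur_xy = best_xy.copy()
        cur_f = _clearance(cur_xy[None, :], axy, adz2, avdw)[0]
        opt_xy, opt_f = cur_xy.copy(), cur_f
        step, temp = p.initial_step, p.initial_temperature
        steps = rng.normal(size=(p.n_proposals, 2))
        accept_u = rng.random(p.n_proposals)
        for k in range(p.n_proposals):
            if k and k % p.decay_every == 0:
                step *= p.decay
                temp *= p.decay
            cand = cur_xy + step * steps[k]
            f = _clearance(cand[None, :], axy, adz2, avdw)[0]
            if f >= cur_f or accept_u[k] < np.exp((f - cur_f) / max(temp, 1e-12)):
                cur_xy, cur_f = cand, f
                if f > opt_f:
                    opt_xy, opt_f = cand.copy(), f
        radii[si] = max(opt_f, 0.0)
        best_xy = opt_xy
    return RadiusProfile(z_values=z_values, radii=radii)


def radius_profile_grid(frame: Frame, structure: Structure, atoms: AtomSelection,
                        pore_frame: PoreFrame, z_range: tuple[float, float],
                        z_step: float, extent: float = 8.0,
                        final_step: float = 0.005,
                        z_cutoff: float = 8.0) -> RadiusProfile:
    """Reference profiler: exhaustive coarse-to-fine 2D grid search.

    Independent of the annealing path; used as a slow oracle.  On a
    coarse grid (half-width ``extent`` Å around the axis) the search is
    restricted to the connected positive-clearance region containing
    the axis — the lumen — so the probe cannot jump across the wall
    into open space, where the clearance of a finite atom cluster grows
    without bound.  The best lumen point is then refined on
    progressively finer local grids down to ``final_step`` Å.
    """
    from scipy import ndimage

    if z_step <= 0:
        raise ValueError("z_step must be positive")
    coords, vdw = _pore_coords(frame, structure, atoms, pore_frame)
    n_slices = int(round((z_range[1] - z_range[0]) / z_step)) + 1
    z_values = z_range[0] + z_step * np.arange(n_slices)
    radii = np.empty(n_slices)
    for si, z in enumerate(z_values):
        dz = coords[:, 2] - z
        mask = np.abs(dz) <= z_cutoff
        if not mask.any():
            radii[si] = np.inf
            continue
        axy, adz2, avdw = coords[mask, :2], dz[mask] ** 2, vdw[mask]

        # coarse pass: lumen = connected f>0 component containing the axis
        step = float(extent) / 40.0
        g = np.arange(-extent, extent + step / 2, step)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        f = _clearance(pts, axy, adz2, avdw).reshape(xx.shape)
        labels, _ = ndimage.label(f > 0)
        ci = len(g) // 2  # the axis cell
        lumen = labels == labels[ci, ci] if labels[ci, ci] else np.zeros_like(f, bool)
        if lumen.any():
            k = np.argmax(np.where(lumen, f, -np.inf))
        else:  # blocked slice: best (least-negative) clearance near the axis
            k = np.argmax(f)
        best_xy = pts[k]
        best_f = f.ravel()[k]

        # local refinement around the lumen optimum
        half = 1.5 * step
        step /= 5.0
        while True:
            g = np.arange(-half, half + step / 2, step)
            xx, yy = np.meshgrid(best_xy[0] + g, best_xy[1] + g, indexing="ij")
            p2 = np.column_stack([xx.ravel(), yy.ravel()])
            f2 = _clearance(p2, axy, adz2, avdw)
            k = int(np.argmax(f2))
            best_xy, best_f = p2[k], float(f2[k])
            if step <= final_step:
                break
            half, step = 1.5 * step, step / 5.0
        radii[si] = max(best_f, 0.0)
    return RadiusProfile(z_values=z_values, radii=radii)


def classify_profile(profile: RadiusProfile,
                     thresholds: tuple[float, ...] = (1.2,)) -> RadiusProfile:
    """Attach per-slice labels by radius threshold (default 1.2 Å).

    Strict comparison: r < threshold → ``sub_threshold``; r ≥ threshold
    → ``open``.  With several thresholds the label names the band
    (``<1.2``, ``1.2–3``, ``>=3`` ...).  Radii are left unchanged.
    """
    thr = tuple(sorted(float(t) for t in thresholds))
    if not thr:
        raise ValueError("need at least one threshold")
    if len(thr) == 1:
        labels = np.where(profile.radii < thr[0], "sub_threshold", "open")
    else:
        names = ["<%.3g" % thr[0]] + [
            "%.3g–%.3g" % (a, b) for a, b in zip(thr[:-1], thr[1:])
        ] + [">=%.3g" % thr[-1]]
        idx = np.searchsorted(thr, profile.radii, side="right")
        labels = np.array(names, dtype=object)[idx]
    return RadiusProfile(z_values=profile.z_values, radii=profile.radii,
                         classification=np.asarray(labels, dtype=object),
                         thresholds=thr)
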