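"""Core in-memory containers shared by every analysis stage.

Conventions: coordinates and radii in Å, times in ns, atom indices
0-based and contiguous.  Boxes are orthogonal (three edge lengths);
triclinic inputs are accepted at the file boundary but only the
diagonal lengths are kept, and coordinates are assumed pre-wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["Structure", "Frame", "Trajectory", "AtomSelection"]


@dataclass
class Structure:
    """Static topology-lite description of a system.

    Per-atom attribute arrays, all of length ``n_atoms``.  ``coordinates``
    holds the reference (model) coordinates, e.g. from the PDB record;
    per-frame coordinates live in :class:`Frame`.
    """

    names: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray
    chains: np.ndarray
    elements: np.ndarray
    vdw_radii: np.ndarray
    coordinates: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("residue_names", "residue_ids", "chains", "elements", "vdw_radii"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"attribute {attr!r} length != n_atoms ({n})")
        if np.any(np.asarray(self.vdw_radii) <= 0):
            raise ValueError("all atoms must carry a positive vdW radius")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.n_atoms)


@dataclass
class Frame:
    """One trajectory snapshot: time (ns), coordinates (Å) and box (Å)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if np.any(self.box[:3] <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """In-memory trajectory with a static/mobile atom split.

    Most synthetic systems have a rigid wall plus mobile waters; storing
    only the mobile coordinates per frame keeps 10^4-frame runs small.
    ``moving_indices`` selects the atoms whose coordinates are stored in
    ``moving_coords`` (n_frames, n_moving, 3); every other atom keeps the
    structure's reference coordinates in every frame.
    """

    structure: Structure
    times: np.ndarray
    box: np.ndarray
    moving_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    moving_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.moving_coords is None:
            self.moving_coords = np.empty((len(self.times), 0, 3))
        if self.moving_coords.shape[0] != len(self.times):
            raise ValueError("moving_coords frame count != times length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def frame(self, i: int) -> Frame:
        coords = np.array(self.structure.coordinates, dtype=float, copy=True)
        if len(self.moving_indices):
            coords[self.moving_indices] = self.moving_coords[i]
        return Frame(time=float(self.times[i]), coordinates=coords, box=self.box)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self.frame(i)


@dataclass
class AtomSelection:
    """Ordered, 0-based atom index set with a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)
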