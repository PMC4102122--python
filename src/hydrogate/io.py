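"""Structure/trajectory IO, atom selection and volumetric-grid export.

Readers are thin wrappers around MDAnalysis; everything is converted at
the boundary to the package's own containers (0-based indices, Å, ns).
Files are never mutated; re-reading a file yields identical values.
"""

from __future__ import annotations

import logging
import os
import re
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .core import AtomSelection, Frame, Structure, Trajectory

logger = logging.getLogger("hydrogate")

__all__ = [
    "DEFAULT_VDW_TABLE",
    "read_structure",
    "iter_frames",
    "select",
    "water_oxygens",
    "write_pdb",
    "write_gro",
    "write_trajectory",
    "write_dx",
    "read_dx",
]

#: Element → van der Waals radius (Å).  Element-generic (Bondi-style)
#: rather than force-field specific; override via the ``vdw_table``
#: argument of :func:`read_structure`.
DEFAULT_VDW_TABLE: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

#: Fallback radius for elements missing from the table (warned once each).
FALLBACK_VDW = 1.70

WATER_RESNAMES = {"HOH", "SOL", "TIP3", "WAT"}

_warned_elements: set[str] = set()


def _guess_element(name: str) -> str:
    """Guess an element symbol from an atom name (PDB-style heuristics)."""
    stripped = re.sub(r"[^A-Za-z]", "", name).upper()
    if not stripped:
        return "X"
    if stripped[:2] in {"CL", "BR"}:
        return stripped[:2].capitalize()
    return stripped[0]


def _assign_vdw(elements: np.ndarray, vdw_table: Mapping[str, float]) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = str(el).capitalize()
        if key in vdw_table:
            radii[i] = vdw_table[key]
        else:
            if key not in _warned_elements:
                logger.warning(
                    "unknown element %r: assigning fallback vdW radius %.2f Å",
                    key, FALLBACK_VDW,
                )
                _warned_elements.add(key)
            radii[i] = FALLBACK_VDW
    return radii


def read_structure(path: str | os.PathLike, vdw_table: Mapping[str, float] | None = None) -> Structure:
    """Read a PDB or GRO file into a :class:`Structure`.

    The format is detected from the extension.  vdW radii are assigned
    per element from ``vdw_table`` (default :data:`DEFAULT_VDW_TABLE`);
    unknown elements get 1.70 Å with a logged warning.
    """
    import MDAnalysis as mda

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(path, to_guess=())
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"cannot parse structure file {path!r}: {exc}") from exc
    atoms = u.atoms
    if len(atoms) == 0:
        raise ValueError(f"structure file {path!r} contains zero atoms")

    names = atoms.names.astype(str)
    try:
        elements = np.array([e if e else _guess_element(n)
                             for e, n in zip(atoms.elements, names)], dtype=object)
    except Exception:  # no element column (e.g. GRO)
        elements = np.array([_guess_element(n) for n in names], dtype=object)
    try:
        chains = atoms.chainIDs.astype(str)
    except Exception:
        chains = np.array([""] * len(atoms), dtype=object)

    table = dict(DEFAULT_VDW_TABLE if vdw_table is None else vdw_table)
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float)
    return Structure(
        names=names.astype(object),
        residue_names=atoms.resnames.astype(object),
        residue_ids=atoms.resids.astype(int),
        chains=np.asarray(chains, dtype=object),
        elements=np.asarray([str(e).capitalize() for e in elements], dtype=object),
        vdw_radii=_assign_vdw(elements, table),
        coordinates=atoms.positions.astype(float).copy(),
        box=box,
    )


def _trajectory_reader(path: str):
    import MDAnalysis as mda

    ext = os.path.splitext(path)[1].lower()
    if ext == ".xtc":
        return mda.coordinates.XTC.XTCReader(path)
    if ext == ".dcd":
        return mda.coordinates.DCD.DCDReader(path)
    raise ValueError(f"unsupported trajectory format {ext!r} (use .xtc or .dcd)")


def iter_frames(path: str | os.PathLike, structure: Structure, stride: int = 1) -> Iterator[Frame]:
    """Stream frames from an XTC/DCD file as :class:`Frame` objects.

    Times are converted from the file's picoseconds to ns.  Frames must
    have the structure's atom count and non-decreasing times.
    """
    path = os.fspath(path)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    reader = _trajectory_reader(path)
    if reader.n_atoms != structure.n_atoms:
        raise ValueError(
            f"trajectory has {reader.n_atoms} atoms but structure has "
            f"{structure.n_atoms}"
        )
    last_time = -np.inf
    for i, ts in enumerate(reader):
        if i % stride:
            continue
        try:
            t_ns = float(ts.time) / 1000.0
            coords = ts.positions.astype(float).copy()
            box = np.asarray(ts.dimensions[:3], dtype=float)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"corrupt frame {i} in {path!r}: {exc}") from exc
        if t_ns < last_time:
            raise ValueError(f"frame {i} time {t_ns} ns decreases (file out of order)")
        last_time = t_ns
        yield Frame(time=t_ns, coordinates=coords, box=box)
    reader.close()


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_FIELD_ALIASES = {
    "atom_name": "names",
    "name": "names",
    "residue_name": "residue_names",
    "resname": "residue_names",
    "residue_id": "residue_ids",
    "resid": "residue_ids",
    "chain": "chains",
    "element": "elements",
}


def _eval_condition(structure: Structure, cond: str) -> np.ndarray:
    cond = cond.strip()
    m = re.match(r"^(\w+)\s+in\s+(.+)$", cond)
    if m:
        field, values = m.group(1), [v.strip() for v in m.group(2).split(",")]
        op = "in"
    else:
        m = re.match(r"^(\w+)\s+startswith\s+(\S+)$", cond)
        if m:
            field, values, op = m.group(1), [m.group(2)], "startswith"
        else:
            m = re.match(r"^(\w+)\s*(!?=)\s*(\S+)$", cond)
            if not m:
                raise ValueError(f"cannot parse selection condition {cond!r}")
            field, op, values = m.group(1), m.group(2), [m.group(3)]
    attr = _FIELD_ALIASES.get(field)
    if attr is None:
        raise ValueError(f"unknown selection field {field!r}")
    col = getattr(structure, attr)
    if attr == "residue_ids":
        col = np.asarray(col, dtype=int)
        vals = [int(v) for v in values]
    else:
        col = np.asarray(col, dtype=str)
        vals = values
    if op == "in":
        return np.isin(col, vals)
    if op == "startswith":
        return np.char.startswith(col.astype(str), vals[0])
    mask = col == vals[0]
    return ~mask if op == "!=" else mask


def select(structure: Structure, expression: str, empty_ok: bool = False,
           label: str | None = None) -> AtomSelection:
    """Resolve a selection expression to an ordered atom-index set.

    Grammar: conditions ``field=value``, ``field!=value``,
    ``field in a,b,c`` and ``field startswith X`` combined with ``and``
    (binds tighter) and ``or``.  Fields: atom_name/name,
    residue_name/resname, residue_id/resid, chain, element.
    """
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for clause in re.split(r"\s+or\s+", expression.strip()):
        clause_mask = np.ones(structure.n_atoms, dtype=bool)
        for cond in re.split(r"\s+and\s+", clause):
            clause_mask &= _eval_condition(structure, cond)
        mask |= clause_mask
    indices = np.flatnonzero(mask)
    if len(indices) == 0 and not empty_ok:
        raise ValueError(f"selection {expression!r} matched no atoms "
                         "(pass empty_ok=True to allow)")
    return AtomSelection(indices=indices, label=label or expression)


def water_oxygens(structure: Structure, empty_ok: bool = False) -> AtomSelection:
    """Preset: oxygen atoms of water residues (HOH/SOL/TIP3/WAT, name O*)."""
    resnames = ",".join(sorted(WATER_RESNAMES))
    return select(structure, f"residue_name in {resnames} and atom_name startswith O",
                  empty_ok=empty_ok, label="water_oxygens")


# ---------------------------------------------------------------------------
# Writers (used by the synthetic generators and the pipeline)
# ---------------------------------------------------------------------------

def _mda_universe(structure: Structure):
    import MDAnalysis as mda

    # group consecutive atoms into residues by (resid, chain, resname) runs
    keys = list(zip(structure.residue_ids, structure.chains, structure.residue_names))
    resindex = np.zeros(structure.n_atoms, dtype=int)
    res_keys = []
    for i, key in enumerate(keys):
        if i and key == keys[i - 1]:
            resindex[i] = resindex[i - 1]
        else:
            resindex[i] = len(res_keys)
            res_keys.append(key)
    n_res = len(res_keys)
    seg_per_res = np.zeros(n_res, dtype=int)
    u = mda.Universe.empty(
        structure.n_atoms, n_residues=n_res, atom_resindex=resindex,
        residue_segindex=seg_per_res, trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in structure.names])
    u.add_TopologyAttr("elements", [str(e) for e in structure.elements])
    u.add_TopologyAttr("chainIDs", [str(c) if c else "A" for c in structure.chains])
    u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
    u.add_TopologyAttr("resids", [int(k[0]) for k in res_keys])
    u.add_TopologyAttr("segids", ["SYS"])
    if structure.coordinates is not None:
        u.atoms.positions = structure.coordinates
    box = structure.box if structure.box is not None else np.array([100.0, 100.0, 100.0])
    u.dimensions = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
    return u


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure (reference coordinates) to a PDB file."""
    u = _mda_universe(structure)
    u.atoms.write(os.fspath(path))


def write_gro(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure (reference coordinates) to a GRO file."""
    u = _mda_universe(structure)
    u.atoms.write(os.fspath(path))


def write_trajectory(trajectory: Trajectory, path: str | os.PathLike) -> None:
    """Write an in-memory trajectory to XTC or DCD (times stored in ps)."""
    import MDAnalysis as mda

    path = os.fspath(path)
    u = _mda_universe(trajectory.structure)
    box = trajectory.box
    dims = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
    kwargs = {}
    if path.lower().endswith(".xtc"):
        kwargs["precision"] = 4  # decimal places in nm: 1e-4 nm → 1e-3 Å
    elif path.lower().endswith(".dcd"):
        # DCD stores only a per-file time step in its header
        times = trajectory.times
        dt_ps = float(np.median(np.diff(times)) * 1000.0) if len(times) > 1 else 1.0
        kwargs["dt"] = dt_ps
    with mda.Writer(path, n_atoms=trajectory.n_atoms, **kwargs) as w:
        for i, frame in enumerate(trajectory):
            u.atoms.positions = frame.coordinates
            u.trajectory.ts.time = frame.time * 1000.0  # ns → ps
            u.trajectory.ts.frame = i
            u.trajectory.ts.dimensions = dims
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# OpenDX scalar grids
# ---------------------------------------------------------------------------

def write_dx(grid, path: str | os.PathLike, field: str = "normalized") -> None:
    """Write a density grid as an OpenDX scalar field.

    ``grid`` needs ``origin`` (lower corner, Å), ``spacing`` (Å) and the
    requested value array (3D).  Values are written in the standard
    OpenDX order (last index, z, varies fastest); the DX origin is the
    centre of the first voxel, so third-party readers place voxel values
    at voxel centres.
    """
    values = np.asarray(getattr(grid, field), dtype=float)
    if values.ndim != 3:
        raise ValueError("grid values must be a 3D array")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite grid value at voxel {tuple(int(i) for i in bad)}")
    origin = np.asarray(grid.origin, dtype=float) + 0.5 * float(grid.spacing)
    d = float(grid.spacing)
    nx, ny, nz = values.shape
    flat = values.ravel(order="C")
    with open(os.fspath(path), "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.6f} {origin[1]:.6f} {origin[2]:.6f}\n")
        fh.write(f"delta {d:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {d:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} "
                 "data follows\n")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.10g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, float]:
    """Read an OpenDX scalar field written by :func:`write_dx`.

    Returns ``(values, origin_lower_corner, spacing)``.
    """
    counts = origin = None
    deltas: list[float] = []
    values: list[float] = []
    with open(os.fspath(path)) as fh:
        for line in fh:
            t = line.split()
            if not t:
                continue
            if t[0] == "object" and "gridpositions" in line:
                counts = tuple(int(v) for v in t[-3:])
            elif t[0] == "origin":
                origin = np.array([float(v) for v in t[1:4]])
            elif t[0] == "delta":
                deltas.append(max(float(v) for v in t[1:4]))
            elif t[0] in {"attribute", "component"} or t[1:2] == ['"density"']:
                continue
            elif t[0] == "object":
                continue
            else:
                values.extend(float(v) for v in t)
    if counts is None or origin is None or not deltas:
        raise ValueError(f"{path!r} is not a parseable DX scalar field")
    spacing = deltas[0]
    arr = np.array(values).reshape(counts, order="C")
    return arr, origin - 0.5 * spacing, spacing
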