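"""Config-driven end-to-end runs and WT-vs-mutant comparison reports.

A run config (YAML) describes one system — either file inputs
(structure + trajectory + umbrella windows) or a synthetic block — plus
selections, the gate region, grid/profile/WHAM settings, a seed and an
output directory.  Every runner writes plain-text artifacts (TSV, DX,
JSON) plus a provenance block (config hash, seed, versions), and is
byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Iterable

import numpy as np
import yaml

from . import __version__
from .core import Frame, Structure, Trajectory
from .geometry import AnnealParams, classify_profile, compute_pore_frame, radius_profile
from .hydration import (GridSpec, SlabRegion, occupancy_histogram,
                        occupancy_series, summarize_occupancy, water_density_grid)
from .io import iter_frames, read_structure, select, water_oxygens, write_dx
from .synthetic import (AnalyticPMF, PoreSpec, WettingParams,
                        gen_umbrella_samples, gen_wetting_trajectory)
from .wham import KT_310K, compare_pmfs, read_window, to_pmf, wham

logger = logging.getLogger("hydrogate")

__all__ = [
    "load_config",
    "config_hash",
    "run_hydration",
    "run_profile",
    "run_pmf",
    "run_compare",
]

DEFAULT_REGION = {"z_lo": -10.0, "z_hi": -5.0, "radial_cutoff": None}


def load_config(path: str | os.PathLike) -> dict:
    with open(os.fspath(path)) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path!r} must be a YAML mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    system = cfg.get("system", {})
    has_files = "files" in system
    has_synth = "synthetic" in system
    if has_files == has_synth:
        raise ValueError(
            "config error at system: exactly one of 'files' or 'synthetic' "
            "must be present")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stride", 1)
    cfg.setdefault("region", dict(DEFAULT_REGION))
    cfg.setdefault("selections", {})
    cfg["selections"].setdefault("water", "water_oxygens")
    cfg["selections"].setdefault("reference",
                                 "residue_id=117 or residue_id=225")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _provenance(cfg: dict, seed: int) -> dict:
    return {
        "config_sha256": config_hash(cfg),
        "seed": int(seed),
        "hydrogate_version": __version__,
        "numpy_version": np.__version__,
    }


def _write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(path: str, header: list[str], columns: list[np.ndarray]) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(header) + "\n")
        for row in zip(*columns):
            fh.write("\t".join(f"{v:.8g}" if isinstance(v, (float, np.floating))
                               else str(v) for v in row) + "\n")


def _build_system(cfg: dict, seed: int) -> tuple[Structure, Iterable[Frame], dict]:
    """Resolve a config's system block to (structure, frames, extras)."""
    system = cfg["system"]
    if "synthetic" in system:
        synth = system["synthetic"]
        pore_cfg = dict(synth.get("pore", {}))
        for key in ("radius_knots", "constriction_zone"):
            if key in pore_cfg:
                val = pore_cfg[key]
                pore_cfg[key] = tuple(tuple(x) for x in val) \
                    if key == "radius_knots" else tuple(val)
        spec = PoreSpec(**pore_cfg)
        wet_cfg = dict(synth.get("wetting", {}))
        wet_cfg["seed"] = seed
        params = WettingParams(**wet_cfg)
        traj, states = gen_wetting_trajectory(spec, params)
        return traj.structure, traj, {"pore_spec": spec, "states": states}
    files = system["files"]
    structure = read_structure(files["structure"])
    frames = iter_frames(files["trajectory"], structure,
                         stride=int(cfg.get("stride", 1)))
    return structure, frames, {"windows": files.get("windows", [])}


def _selections(cfg: dict, structure: Structure):
    sel_cfg = cfg["selections"]
    water = water_oxygens(structure) if sel_cfg["water"] == "water_oxygens" \
        else select(structure, sel_cfg["water"])
    ref = select(structure, sel_cfg["reference"])
    return water, ref


def run_hydration(cfg: dict, outdir: str | os.PathLike | None = None,
                  seed: int | None = None) -> dict:
    """Occupancy series, histogram, summary and density map for one system.

    Artifacts in the output directory: ``occupancy.tsv`` (time_ns,
    n_waters), ``histogram.tsv``, ``summary.json``, ``density.dx``,
    ``provenance.json``.  Returns the report section as a dict.
    """
    cfg = validate_config(dict(cfg))
    seed = int(cfg["seed"] if seed is None else seed)
    outdir = os.fspath(outdir or cfg.get("outdir", "hydrogate_out"))
    os.makedirs(outdir, exist_ok=True)

    structure, frames, extras = _build_system(cfg, seed)
    water, ref = _selections(cfg, structure)
    region = SlabRegion(**cfg["region"])

    if isinstance(frames, Trajectory):
        traj_for_series: Iterable[Frame] = frames
        traj_for_grid: Iterable[Frame] = frames
    else:  # a one-shot file stream: materialise
        frame_list = list(frames)
        traj_for_series = frame_list
        traj_for_grid = frame_list

    series = occupancy_series(traj_for_series, water, ref, region,
                              stride=int(cfg.get("stride", 1))
                              if isinstance(traj_for_series, Trajectory) else 1)
    hist = occupancy_histogram(series)
    summary = summarize_occupancy(series)

    grid_cfg = cfg.get("grid", {})
    spacing = float(grid_cfg.get("spacing", 0.5))
    if "lower" in grid_cfg and "upper" in grid_cfg:
        gspec = GridSpec.covering(grid_cfg["lower"], grid_cfg["upper"], spacing)
    else:
        pf = compute_pore_frame(next(iter(traj_for_grid)) if not
                                isinstance(traj_for_grid, Trajectory)
                                else traj_for_grid.frame(0), ref)
        half = float(grid_cfg.get("half_width", 8.0))
        lower = pf.origin + np.array([-half, -half, region.z_lo - 2.0])
        upper = pf.origin + np.array([half, half, region.z_hi + 2.0])
        gspec = GridSpec.covering(lower, upper, spacing)
    grid = water_density_grid(traj_for_grid, water, gspec)

    _write_tsv(os.path.join(outdir, "occupancy.tsv"), ["time_ns", "n_waters"],
               [series.times, series.counts])
    _write_tsv(os.path.join(outdir, "histogram.tsv"), ["n_waters", "probability"],
               [hist.count_values, hist.probabilities.astype(float)])
    write_dx(grid, os.path.join(outdir, "density.dx"))

    report = {
        "label": cfg.get("system", {}).get("label", "system"),
        "n_frames": summary.n_frames,
        "mu": summary.mu,
        "mu_se": float(np.std(series.counts, ddof=1) / np.sqrt(len(series)))
        if len(series) > 1 else 0.0,
        "fraction_zero": summary.fraction_zero,
        "p_zero_histogram": hist.probability_of(0),
        "mean_dwell_dry_ns": summary.mean_dwell("dry"),
        "mean_dwell_wet_ns": summary.mean_dwell("wet"),
        "density_isovoxels_0.5": grid.isosurface_voxel_count(0.5),
        "density_overflow": grid.overflow,
    }
    _write_json({**report, "provenance": _provenance(cfg, seed)},
                os.path.join(outdir, "summary.json"))
    _write_json(_provenance(cfg, seed), os.path.join(outdir, "provenance.json"))
    return report


def run_profile(cfg: dict, outdir: str | os.PathLike | None = None,
                seed: int | None = None) -> dict:
    """Radius profile of the first frame, classified at 1.2 Å."""
    cfg = validate_config(dict(cfg))
    seed = int(cfg["seed"] if seed is None else seed)
    outdir = os.fspath(outdir or cfg.get("outdir", "hydrogate_out"))
    os.makedirs(outdir, exist_ok=True)

    structure, frames, extras = _build_system(cfg, seed)
    _, ref = _selections(cfg, structure)
    frame0 = frames.frame(0) if isinstance(frames, Trajectory) else next(iter(frames))
    pf = compute_pore_frame(frame0, ref)

    prof_cfg = cfg.get("profile", {})
    z_min = float(prof_cfg.get("z_min", -15.0))
    z_max = float(prof_cfg.get("z_max", 15.0))
    z_step = float(prof_cfg.get("z_step", 1.0))
    pore_sel = select(structure, prof_cfg.get("selection", "residue_name=WAL"),
                      empty_ok=True)
    if len(pore_sel) == 0:
        pore_sel = select(structure, "residue_name!=SOL")
    search = AnnealParams(**prof_cfg.get("search", {}))
    profile = radius_profile(frame0, structure, pore_sel, pf,
                             (z_min, z_max), z_step, search=search, seed=seed)
    profile = classify_profile(profile,
                               tuple(prof_cfg.get("thresholds", (1.2,))))
    _write_tsv(os.path.join(outdir, "profile.tsv"),
               ["z_A", "radius_A", "class"],
               [profile.z_values, profile.radii, profile.classification])
    report = {"min_radius_A": profile.min_radius,
              "z_at_min_A": profile.z_at_min,
              "n_sub_threshold": int(np.sum(
                  profile.classification == "sub_threshold"))}
    _write_json({**report, "provenance": _provenance(cfg, seed)},
                os.path.join(outdir, "profile_summary.json"))
    return report


def _pmf_windows(cfg: dict, seed: int) -> list:
    pmf_cfg = cfg.get("pmf", {})
    if "synthetic" in pmf_cfg:
        s = pmf_cfg["synthetic"]
        pmf = AnalyticPMF(form=s.get("form", "gaussian_barrier"),
                          params=dict(s.get("params",
                                            {"height": 5.0, "width": 2.0,
                                             "center": -7.5})),
                          domain=tuple(s.get("domain", (-20.0, 4.0))))
        n_win = int(s.get("n_windows", 25))
        start = float(s.get("centers_start", pmf.domain[0]))
        step = float(s.get("spacing", 1.0))
        centers = start + step * np.arange(n_win)
        return gen_umbrella_samples(
            pmf, centers, k_bias=float(s.get("k_bias", 10.0)),
            kT=float(s.get("kT", KT_310K)),
            n_per_window=int(s.get("n_per_window", 10000)),
            seed=seed)
    paths = cfg.get("system", {}).get("files", {}).get("windows", [])
    if not paths:
        raise ValueError("config error at pmf: no synthetic block and no "
                         "window files under system.files.windows")
    return [read_window(p) for p in paths]


def run_pmf(cfg: dict, outdir: str | os.PathLike | None = None,
            seed: int | None = None) -> dict:
    """WHAM over the configured windows; writes PMF and convergence log."""
    cfg = validate_config(dict(cfg))
    seed = int(cfg["seed"] if seed is None else seed)
    outdir = os.fspath(outdir or cfg.get("outdir", "hydrogate_out"))
    os.makedirs(outdir, exist_ok=True)

    windows = _pmf_windows(cfg, seed)
    wham_cfg = cfg.get("pmf", {}).get("wham", {})
    sol = wham(windows,
               bin_width=float(wham_cfg.get("bin_width", 0.1)),
               tolerance=float(wham_cfg.get("tolerance", 1e-6)),
               max_iter=int(wham_cfg.get("max_iter", 100_000)))
    pmf = to_pmf(sol, reference=wham_cfg.get("reference", "bulk_end"))

    _write_tsv(os.path.join(outdir, "pmf.tsv"), ["z_A", "G_kT"],
               [pmf.z, pmf.G])
    with open(os.path.join(outdir, "wham_convergence.log"), "w") as fh:
        fh.write(f"# windows={len(windows)} bin_width={sol.bin_width} "
                 f"tolerance={sol.tolerance} kT={sol.kT}\n")
        fh.write("# iteration\tmax_abs_dF_kJ_mol\n")
        for i, r in enumerate(sol.residual_history, start=1):
            fh.write(f"{i}\t{r:.8g}\n")
        fh.write(f"# converged={sol.converged} iterations={sol.iterations}\n")
    report = {"converged": bool(sol.converged),
              "iterations": int(sol.iterations),
              "barrier_kT": pmf.barrier_height,
              "n_windows": len(windows)}
    _write_json({**report, "provenance": _provenance(cfg, seed)},
                os.path.join(outdir, "pmf_summary.json"))
    return report


def run_compare(cfg_a: dict, cfg_b: dict,
                outdir: str | os.PathLike = "hydrogate_compare",
                seed: int | None = None,
                region: tuple[float, float] | None = None) -> dict:
    """Full A-vs-B comparison (conventionally A = mutant, B = WT).

    Runs hydration for both systems (and PMF where configured), then
    reports Δμ = μ_A − μ_B with its standard error, the histogram
    overlay and, when both PMFs exist, ΔG = G_A − G_B with peak and
    positive area.  Writes ``comparison.json`` and ``delta_pmf.tsv``.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    report: dict = {}
    sections = {}
    pmfs = {}
    for tag, cfg in (("a", cfg_a), ("b", cfg_b)):
        cfg = validate_config(dict(cfg))
        sub = os.path.join(outdir, tag)
        sections[tag] = run_hydration(cfg, outdir=sub, seed=seed)
        if "pmf" in cfg:
            run_pmf(cfg, outdir=sub, seed=seed)
            windows = _pmf_windows(cfg, int(cfg["seed"] if seed is None else seed))
            wham_cfg = cfg.get("pmf", {}).get("wham", {})
            sol = wham(windows,
                       bin_width=float(wham_cfg.get("bin_width", 0.1)),
                       tolerance=float(wham_cfg.get("tolerance", 1e-6)),
                       max_iter=int(wham_cfg.get("max_iter", 100_000)))
            pmfs[tag] = to_pmf(sol, reference=wham_cfg.get("reference", "bulk_end"))
    mu_a, mu_b = sections["a"]["mu"], sections["b"]["mu"]
    # naive SE of Δμ from per-frame count variance (no autocorrelation model)
    report["delta_mu"] = mu_a - mu_b
    report["delta_mu_se"] = float(np.hypot(sections["a"]["mu_se"],
                                           sections["b"]["mu_se"]))
    report["systems"] = sections
    if set(pmfs) == {"a", "b"}:
        cmp_rec = compare_pmfs(pmfs["a"], pmfs["b"], region=region)
        report["delta_pmf_peak_kT"] = cmp_rec.peak_delta
        report["delta_pmf_positive_area_kT_A"] = cmp_rec.positive_area
        _write_tsv(os.path.join(outdir, "delta_pmf.tsv"), ["z_A", "dG_kT"],
                   [cmp_rec.z, cmp_rec.delta_G])
    prov = {"config_a_sha256": config_hash(validate_config(dict(cfg_a))),
            "config_b_sha256": config_hash(validate_config(dict(cfg_b))),
            "seed": seed, "hydrogate_version": __version__}
    _write_json({**report, "provenance": prov},
                os.path.join(outdir, "comparison.json"))
    return report
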