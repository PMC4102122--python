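"""1D umbrella-sampling reconstruction by the weighted histogram method.

Windows are harmonically biased samples of a reaction coordinate z (the
ion's axial position in the pore frame).  The standard self-consistent
WHAM equations are iterated to convergence:

    P(z_b) = Σ_i n_i(z_b) / Σ_i N_i exp[(F_i − U_i(z_b)) / kT]
    exp(−F_i / kT) = Σ_b P(z_b) exp(−U_i(z_b) / kT)

with U_i(z) = ½ k (z − z_i)² and the gauge F_1 = 0.  The PMF follows as
G(z) = −kT ln P(z), reported in kT units relative to a reference bin
(default: the most cytoplasmic sampled bin, i.e. the bulk end).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger("hydrogate")

__all__ = [
    "KT_310K",
    "UmbrellaWindow",
    "WHAMSolution",
    "PMFProfile",
    "PMFComparison",
    "bias_energy",
    "wham",
    "to_pmf",
    "compare_pmfs",
    "write_window",
    "read_window",
]

#: kT at 310 K in kJ/mol (k_B = 0.0083145 kJ mol⁻¹ K⁻¹).
KT_310K = 0.0083145 * 310.0


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias parameters plus z samples (Å)."""

    center: float
    force_constant: float  # kJ mol⁻¹ Å⁻²
    kT: float              # kJ mol⁻¹
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.samples.size == 0:
            raise ValueError("window must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


def bias_energy(window: UmbrellaWindow, z) -> np.ndarray:
    """Harmonic bias U_i(z) = ½ k (z − z_i)², kJ/mol."""
    z = np.asarray(z, dtype=float)
    return 0.5 * window.force_constant * (z - window.center) ** 2


@dataclass
class WHAMSolution:
    bin_centers: np.ndarray
    probabilities: np.ndarray      # unbiased P(z_b), sums to 1 over bins
    window_free_energies: np.ndarray  # F_i, kJ/mol, gauge F_1 = 0
    kT: float
    bin_width: float
    iterations: int
    converged: bool
    tolerance: float
    mask: np.ndarray = field(default=None)  # True where bin is unsampled
    residual_history: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.bin_centers), dtype=bool)


def _window_overlaps(windows: list[UmbrellaWindow], edges: np.ndarray) -> None:
    """Hard error if any window's histogram shares no bin with any other."""
    if len(windows) < 2:
        return
    hists = [np.histogram(w.samples, bins=edges)[0] > 0 for w in windows]
    bad = []
    for i, hi in enumerate(hists):
        if not any(np.any(hi & hj) for j, hj in enumerate(hists) if j != i):
            bad.append(i)
    if bad:
        raise ValueError(
            f"umbrella windows {bad} share no occupied histogram bin with any "
            "other window; the sampled ranges do not overlap"
        )


def wham(windows: list[UmbrellaWindow], bin_width: float = 0.1,
         tolerance: float = 1e-6, max_iter: int = 100_000) -> WHAMSolution:
    """Self-consistent WHAM over a shared-kT set of umbrella windows.

    Bins span all samples at the given width.  Convergence is declared
    when max_i |ΔF_i| < ``tolerance`` (kJ/mol); otherwise the best
    iterate is returned with ``converged=False``.  Interior unsampled
    bins are masked with a warning; a window whose histogram overlaps no
    other window raises.  Deterministic; invariant to window order.
    """
    if not windows:
        raise ValueError("need at least one umbrella window")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    kT = windows[0].kT
    if any(abs(w.kT - kT) > 1e-12 for w in windows):
        raise ValueError("all windows must share the same kT")

    # order-canonical processing (sorted by center) for order invariance
    order = np.argsort([w.center for w in windows], kind="stable")
    ws = [windows[i] for i in order]

    z_min = min(w.samples.min() for w in ws)
    z_max = max(w.samples.max() for w in ws)
    n_bins = max(int(np.ceil((z_max - z_min) / bin_width)), 1)
    edges = z_min + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    _window_overlaps(ws, edges)

    n_ib = np.stack([np.histogram(w.samples, bins=edges)[0] for w in ws])
    n_b = n_ib.sum(axis=0).astype(float)
    N_i = np.array([w.n_samples for w in ws], dtype=float)
    U_ib = np.stack([bias_energy(w, centers) for w in ws])  # (W, B)

    sampled = n_b > 0
    interior = np.zeros_like(sampled)
    if sampled.any():
        lo, hi = np.flatnonzero(sampled)[[0, -1]]
        interior[lo:hi + 1] = True
    masked = interior & ~sampled
    if masked.any():
        logger.warning("WHAM: %d empty bin(s) interior to the sampled range "
                       "masked (z = %s)", masked.sum(),
                       np.round(centers[masked], 2))

    with np.errstate(under="ignore"):
        boltz = np.exp(-U_ib / kT)  # (W, B)
        F = np.zeros(len(ws))
        residuals = []
        converged = False
        it = 0
        P = np.zeros(n_bins)
        for it in range(1, max_iter + 1):
            denom = (N_i * np.exp(F / kT)) @ boltz  # Σ_i N_i e^{(F_i−U_ib)/kT}
            P = np.where(denom > 0, n_b / np.maximum(denom, 1e-300), 0.0)
            P /= P.sum()
            zsum = boltz @ P  # Σ_b P_b e^{−U_ib/kT}
            F_new = -kT * np.log(np.maximum(zsum, 1e-300))
            F_new -= F_new[0]
            resid = float(np.max(np.abs(F_new - F)))
            residuals.append(resid)
            F = F_new
            if resid < tolerance:
                converged = True
                break
    if not converged:
        logger.warning("WHAM did not converge in %d iterations "
                       "(residual %.3g kJ/mol)", max_iter, residuals[-1])
    P = np.where(masked, 0.0, P)
    if P.sum() > 0:
        P = P / P.sum()
    return WHAMSolution(bin_centers=centers, probabilities=P,
                        window_free_energies=F, kT=kT, bin_width=bin_width,
                        iterations=it, converged=converged, tolerance=tolerance,
                        mask=~sampled, residual_history=np.asarray(residuals))


@dataclass
class PMFProfile:
    """Free-energy profile G(z) in kT units, zero at the reference bin."""

    z: np.ndarray
    G: np.ndarray            # kT; NaN on masked bins
    reference: str           # "bulk_end" | "minimum"
    mask: np.ndarray         # True where the bin was unsampled

    @property
    def barrier_height(self) -> float:
        """max G over sampled bins (kT, relative to the reference)."""
        return float(np.nanmax(self.G))


def to_pmf(solution: WHAMSolution, reference: str = "bulk_end") -> PMFProfile:
    """G(z) = −ln P(z) in kT, shifted to zero at the reference.

    ``bulk_end``: the most cytoplasmic (lowest-z) sampled bin —
    barriers then read as work relative to bulk water; ``minimum``: the
    global minimum of G.
    """
    P = solution.probabilities
    sampled = ~solution.mask & (P > 0)
    if not sampled.any():
        raise ValueError("WHAM solution has no sampled bins")
    G = np.full_like(P, np.nan)
    G[sampled] = -np.log(P[sampled])
    if reference == "bulk_end":
        ref_idx = int(np.flatnonzero(sampled)[0])
    elif reference == "minimum":
        ref_idx = int(np.nanargmin(G))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if not sampled[ref_idx]:
        raise ValueError("reference bin is masked")
    G -= G[ref_idx]
    return PMFProfile(z=solution.bin_centers.copy(), G=G,
                      reference=reference, mask=~sampled)


@dataclass
class PMFComparison:
    """Per-bin ΔG = G_a − G_b with region summaries (kT, kT·Å)."""

    z: np.ndarray
    delta_G: np.ndarray
    region: tuple[float, float]
    peak_delta: float        # max ΔG within region, kT
    positive_area: float     # ∫ max(ΔG, 0) dz over region, kT·Å
    bin_width: float


def compare_pmfs(pmf_a: PMFProfile, pmf_b: PMFProfile,
                 region: tuple[float, float] | None = None) -> PMFComparison:
    """Compare two PMFs on pmf_a's bins (pmf_b linearly re-binned).

    Reports ΔG(z) = G_a − G_b, the peak ΔG inside ``region`` and the
    integrated area of positive ΔG over the region (rectangle rule, so a
    uniform offset d over a width L gives area d·L).
    """
    za, zb = pmf_a.z, pmf_b.z
    va = ~pmf_a.mask
    vb = ~pmf_b.mask
    lo = max(za[va].min(), zb[vb].min())
    hi = min(za[va].max(), zb[vb].max())
    if lo >= hi:
        raise ValueError("PMF domains are disjoint; nothing to compare")
    if region is None:
        region = (lo, hi)
    if region[0] >= region[1]:
        raise ValueError("region must satisfy lo < hi")

    same_bins = len(za) == len(zb) and np.allclose(za, zb)
    Gb = pmf_b.G if same_bins else np.interp(za, zb[vb], pmf_b.G[vb],
                                             left=np.nan, right=np.nan)
    dG = pmf_a.G - Gb
    in_region = (za >= region[0]) & (za <= region[1]) & np.isfinite(dG)
    if not in_region.any():
        raise ValueError("no finite overlapping bins inside the region")
    bw = float(np.median(np.diff(za))) if len(za) > 1 else 0.0
    peak = float(np.max(dG[in_region]))
    area = float(np.sum(np.clip(dG[in_region], 0.0, None)) * bw)
    return PMFComparison(z=za.copy(), delta_G=dG, region=tuple(region),
                         peak_delta=peak, positive_area=area, bin_width=bw)


# ---------------------------------------------------------------------------
# Window files: two-column (time_ps, z_Å) + YAML sidecar metadata
# ---------------------------------------------------------------------------

def write_window(window: UmbrellaWindow, path: str | os.PathLike,
                 dt_ps: float = 20e-3) -> None:
    """Write a window as TSV (time_ps, z_A) plus ``<path>.meta.yaml``."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("# time_ps\tz_A\n")
        for i, z in enumerate(window.samples):
            fh.write(f"{i * dt_ps:.6g}\t{z:.8g}\n")
    meta = {"center_A": float(window.center),
            "force_constant_kJ_mol_A2": float(window.force_constant),
            "kT_kJ_mol": float(window.kT)}
    with open(path + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_window(path: str | os.PathLike) -> UmbrellaWindow:
    """Read a window written by :func:`write_window`."""
    path = os.fspath(path)
    with open(path + ".meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    return UmbrellaWindow(center=float(meta["center_A"]),
                          force_constant=float(meta["force_constant_kJ_mol_A2"]),
                          kT=float(meta["kT_kJ_mol"]),
                          samples=data[:, 1])
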