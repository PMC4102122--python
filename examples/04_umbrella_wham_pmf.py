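"""Free-energy profile from umbrella sampling via WHAM.

Draws exact samples from a known 5-kT Gaussian barrier under the
standard umbrella protocol (25 windows every 1 Å, harmonic force
constant 10 kJ mol⁻¹ Å⁻²), reconstructs the profile by self-consistent
WHAM, and compares the recovered barrier to the analytic truth.
"""

import numpy as np

import hydrogate as hg

kT = hg.KT_310K  # 2.577 kJ/mol at 310 K
truth = hg.AnalyticPMF("gaussian_barrier",
                       {"height": 5.0, "width": 2.0, "center": -7.5},
                       domain=(-20.0, 4.0))
centers = -20.0 + np.arange(25.0)  # one window per Å
windows = hg.gen_umbrella_samples(truth, centers, k_bias=10.0, kT=kT,
                                  n_per_window=10_000, seed=123)

solution = hg.wham(windows, bin_width=0.1, tolerance=1e-6)
pmf = hg.to_pmf(solution, reference="bulk_end")

print(f"windows: {len(windows)}, samples/window: {windows[0].n_samples}")
print(f"WHAM converged: {solution.converged} after {solution.iterations} "
      f"iterations (residual < {solution.tolerance} kJ/mol)")
print(f"recovered barrier: {pmf.barrier_height:.2f} kT (truth 5.00 kT)")

print("\n z (A)   G (kT)   truth (kT)")
ok = ~pmf.mask
ref = truth.evaluate(pmf.z[ok][0])
for z in np.arange(-20.0, 4.0, 3.0):
    i = int(np.argmin(np.abs(pmf.z - z)))
    if ok[i]:
        print(f"{pmf.z[i]:6.1f}  {pmf.G[i]:7.2f}  {truth.evaluate(pmf.z[i]) - ref:9.2f}")
print()
print("G(z) is the work (in kT) to move the tagged ion from bulk (z = −20)")
print("along the pore axis; the peak at z = −7.5 is the free-energy barrier")
print("the constriction poses even though it is never sterically closed.")
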