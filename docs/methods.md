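# Methods

## Scope and model

hydrogate analyses hydrophobic gating — the stochastic collapse
("dewetting") of the water column inside an apolar pore constriction —
in ion-channel MD trajectories, and reconstructs the free-energy cost
that a dewetted gate imposes on a permeating ion.  Four quantities are
computed: gate-slab water occupancy over time, bulk-normalized 3D water
density, maximal-sphere pore radius profiles, and 1D potentials of mean
force from umbrella sampling.  A synthetic-data module supplies inputs
with closed-form ground truth; it is first-class, tested code and the
default source for every test and the acceptance script.

Coordinates and radii are in Å, times in ns, energies in kJ/mol
internally and kT in reported profiles.  Atom indexing is 0-based in
memory and 1-based only at file boundaries.  Boxes are treated as
orthogonal; coordinates must be pre-wrapped (periodic imaging is out of
scope for the slab count and grids).

## The pore frame

All axial coordinates are measured in a pore-aligned frame: the origin
(z = 0) is the centroid of a reference selection — for TWIK-1-like
systems, all atoms of the two threonines at the innermost K⁺ site
(residues 117 and 225 on both chains; configurable, e.g. to side-chain
oxygens only) — and the axis is the lab z axis (`fixed_z`, default) or
the dominant principal axis of a pore-lining selection (`principal`),
oriented toward +z.  The cytoplasmic vestibule is at negative z.  The
frame is recomputed per frame for occupancy series.  A selection whose
principal axes are degenerate (isotropic within a relative eigengap of
10⁻⁶) is rejected rather than silently picking a direction.

## Slab occupancy

The gate region is the slab z ∈ [−10, −5) Å: printed region bounds of
the form "−5 Å < z < −10 Å" are read with the bounds swapped (the
literal reading is empty), and the half-open upper bound lets adjacent
slabs tile without double counting.  No radial bound is applied by
default — the region is defined by z only — but a cylindrical cap
(`radial_cutoff`) is available because in open simulation boxes bulk
water shares the slab's z range.  Occupancy n_H2O(t) is the count of
selected water oxygens in the slab per frame; μ is its time mean, the
dry fraction is the share of frames with n_H2O = 0, and
Δμ = μ(mutant) − μ(WT).  Histograms over integer counts pool repeat
runs by concatenation.  Dwell episodes are maximal runs of zero (dry)
or nonzero (wet) frames times the frame spacing; episodes touching the
series boundaries are kept but flagged censored, and the summary's mean
dwell excludes censored episodes by default (geometric episode lengths
are memoryless, so the exclusion is unbiased).

## Density maps

Water-oxygen deposits are accumulated per frame on a regular cubic
grid (0.5-Å voxels by default) by nearest-voxel binning; a Gaussian
kernel was considered and rejected as the default because the binning
must satisfy an exact conservation law — voxel counts plus an overflow
tally for oxygens outside the grid equal the total deposits on every
run — which anchors the normalization test.  Normalized density is
counts / (n_frames · voxel volume · ρ_bulk) with ρ_bulk = 0.0334
molecules Å⁻³ at ambient conditions (optionally estimated from a
user-designated bulk sub-box); 1 = bulk, and the conventional display
isovalue is 0.5.  Grids are exported as standard OpenDX scalar fields
(z index fastest, DX origin at the first voxel centre) so external
viewers and readers interpret them directly.

## Radius profiles

The per-slice pore radius is the maximal-inscribed-sphere measure,

    r(z) = max over in-plane p  of  min over atoms i of (|p − x_i| − vdw_i),

with true 3D distances (the slice constrains only the probe centre).
The in-plane maximisation uses simulated annealing: 2,000 proposals per
slice, Gaussian steps of initial scale 0.5 Å decaying ×0.9 every 100
proposals, uphill always accepted, downhill accepted with Metropolis
probability under a temperature (initial 0.2 Å) annealed on the same
schedule; each slice starts at the previous slice's optimum and ties
break to the first optimum met in the seeded stream.  The schedule is
exposed in `AnnealParams`, and results are deterministic per seed.
Slices with no atom within an 8-Å axial cutoff report +inf with a
warning.  vdW radii are assigned per element from a configurable table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; unknown elements
1.70 Å with a warning) — element-generic rather than force-field
specific, since the profile is a geometric, not energetic, measure.

An independent reference profiler (`radius_profile_grid`) does an
exhaustive coarse-to-fine grid search.  Because the clearance function
of a finite atom cluster grows without bound outside the wall, the
coarse pass restricts the search to the connected positive-clearance
component containing the axis (the lumen) before refining; the
annealed and grid profilers agree to ~10⁻³ Å on the test pores.
Classification against thresholds (default 1.2 Å) uses a strict
inequality: r < 1.2 Å is `sub_threshold`, r ≥ 1.2 Å is `open`.
Curved-pathway pore walking is out of scope; the pores of interest and
all fixtures are near-axial.

## Umbrella sampling and WHAM

Windows carry a centre z_i, harmonic force constant k (bias
U_i(z) = ½k(z − z_i)²), kT and their z samples; on disk they are
two-column (time_ps, z_Å) TSVs with a YAML sidecar.  The default
protocol shape is 25 windows every 1 Å with k = 10 kJ mol⁻¹ Å⁻²; the
restraint is interpreted as acting on the z coordinate only.  kT
defaults to 2.577 kJ/mol (T = 310 K, k_B = 0.0083145 kJ mol⁻¹ K⁻¹);
the temperature is configurable and recorded in the convergence log.

The standard self-consistent 1D WHAM equations

    P(z_b) = Σ_i n_i(z_b) / Σ_i N_i exp[(F_i − U_i(z_b))/kT]
    exp(−F_i/kT) = Σ_b P(z_b) exp(−U_i(z_b)/kT)

are iterated with P renormalized every iteration, gauge F₁ = 0
(windows processed in centre order, making the result invariant to
input order), bin width 0.1 Å, tolerance max|ΔF_i| < 10⁻⁶ kJ/mol and
an iteration cap of 10⁵ (non-convergence returns the best iterate,
flagged).  The 0.1-Å bin width over-resolves the 1-Å window spacing
without producing empty-bin pathologies at the tested sample sizes;
halving it from 0.2 Å moves recovered barrier heights by < 0.1 kT.
Interior empty bins are masked with a warning; a window whose sample
histogram shares no occupied bin with any other window is a hard error
naming the windows.  No autocorrelation correction or bootstrap is
applied by default (exact i.i.d. synthetic samples need none); the
AR(1) option on the sampler exists to emulate correlated MD input.

The PMF is G(z) = −ln P(z) in kT, zeroed by default at the most
cytoplasmic sampled bin (bulk end), so barriers read as work relative
to bulk water; a global-minimum reference is available.  Profile
comparison re-bins the second profile by linear interpolation where
needed and reports ΔG(z), its peak within a region, and the rectangle
-rule integral of positive ΔG (so a uniform d-kT offset over L Å gives
d·L kT·Å).

## Synthetic ground truth

**Pore walls.**  Pseudo-atoms are placed on rings of radius
r(z) + vdw_wall at axial steps of the wall spacing (default 1 Å, ring
phase randomised per ring), so the inscribed probe radius at z equals
the prescribed piecewise-linear profile r(z).  Two reference
pseudo-atoms (residues 117/225, chains A/B) are embedded in the z = 0
ring; their centroid sits on the axis at z = 0.  The construction
identity is exact for a cylinder and holds to within ~0.03 Å for
sloped walls up to slope ≈ 0.15 (the perpendicular clearance of a cone
is r·cos θ, and ring discretisation adds a term of order
(Δz/2)²/2r); the default hourglass (5-Å ends, 2-Å waist at z = −7.5,
60-Å axis) keeps slopes at or below 0.15 so the analytic profile is a
valid 0.1-Å oracle.

**Wetting trajectories.**  Gate occupancy follows a two-state
continuous-time Markov (telegraph) process — the simplest process
reproducing bimodal wet/dry switching — sampled at the frame interval:
wet→dry rate k_dry, dry→wet rate k_wet, exact per-frame switch
probabilities (k/ρ)(1 − e^(−ρ·dt)) with ρ = k_dry + k_wet, initial
state drawn from the stationary law by default.  Wet frames hold
Poisson(λ_full) oxygens placed uniformly in the constriction volume;
dry frames hold none.  A constant-count ideal-gas water background at
bulk density fills the rest of the pore plus a 10-Å cytoplasmic
reservoir, so density-map normalization has a known truth of 1; the
fixed-size water pool keeps the atom count constant across frames
(trajectory formats require it), with unused slab waters parked far
below every analysis region.  Defaults are the study conditions:
frame_dt = 0.1 ns, 1000 frames (one 100-ns run), λ_full = 12 (a
hydrated gate's occupancy), and rates k_dry = 1.2, k_wet = 0.8 /ns
giving a stationary dry fraction of 0.6 — a gate that is dry slightly
more than half the time.  The rates themselves are free parameters of
the emulation, not fitted quantities.

Sampling at a finite frame interval makes observed dwell episodes
geometric in frames, with mean dt/p_switch — biased above the
continuous 1/k by O(ρ·dt).  The generator exposes both the continuous
and the exact sampled-chain values; recovery tests compare against the
sampled-chain values, and the dry-fraction standard error accounts for
the frame-to-frame autocorrelation φ = e^(−ρ·dt).

**Umbrella windows.**  Samples are drawn i.i.d. from the biased
Boltzmann density ∝ exp(−(G(z) + U_i(z))/kT) by inverse-CDF lookup on
a ≤ 0.01-Å grid — exact sampling by construction, so WHAM validation
is free of autocorrelation confounds.  An optional Gaussian-copula
AR(1) parameter correlates the uniform driver (marginals stay exact)
to emulate MD autocorrelation.  Analytic PMF forms: flat, harmonic,
Gaussian barrier, symmetric double well.  The default samples per
window, 62,500, corresponds to 1.25 ns sampled every 20 fs; the
validation protocol uses 10⁴.

**What the generator does not emulate.**  No molecular dynamics, force
fields, or water–water interactions: occupancy is phenomenological,
water positions are spatially uncorrelated within frames, the wall is
rigid, and umbrella samples are (optionally AR(1)-correlated)
exact draws rather than trajectory output.  Passing tests therefore
demonstrate the correctness of the *analysis* — counting, geometry,
normalization, WHAM inference — under known laws, not the physics of
any real channel; quantities tied to the original all-atom
trajectories (e.g. a specific Δμ or a ~4-kT barrier change) are
reproduced only as constructed synthetic contrasts.

## Pipeline and determinism

Runners consume a YAML config holding exactly one input source per
system (file paths or a synthetic block), selections, region, grid,
WHAM settings, a seed and an output directory.  Artifacts are plain
text — occupancy/histogram/profile/PMF TSVs, OpenDX grids, JSON
summaries, a WHAM convergence log — plus a provenance block (SHA-256
of the canonical config, seed, package and numpy versions).  No
timestamps enter any artifact; all floats are written with fixed
formats; reruns with identical config and seed are byte-identical.
Processing is single-threaded.  Warnings (masked bins, overflow
voxels) go to the `hydrogate` logger; errors abort with a non-zero
exit code at the CLI.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 1,000 randomized
fixtures for the counting oracle; 1-Å slices over ±15 Å for the
profile oracles; a 3×3 grid of (k_dry, k_wet) ∈ {0.5, 1, 2}² at 10⁴
frames for telegraph recovery (3-standard-error bands); a 20-Å bulk
box over 200 frames for density normalization (±5%); the 25-window
protocol at 10⁴ samples/window for 3-kT and 5-kT barrier recovery
(±0.3 kT) plus a 10⁵-sample unbiased window for Boltzmann-inversion
RMSE (< 0.15 kT); and a constructed 4-kT/10-Å profile pair for the
comparison arithmetic (peak ±0.5 kT, area ±5 kT·Å).  These sizes give
comfortable statistical margins while the whole suite runs in well
under a minute of compute per stage.

## Known limitations

* `fixed_z` occupancy is invariant under translations but not
  rotations of the lab frame; use `principal` axis mode for tumbling
  systems.
* The maximal-sphere search assumes a near-axial, simply connected
  lumen; branched or strongly curved channels need a pathfinding
  profiler.
* WHAM assumes uncorrelated samples within windows; feed decorrelated
  (strided) MD data or expect underestimated uncertainty (no error
  bars are produced by default).
* The telegraph emulation has exponential dwell times; real gates may
  show heavy-tailed or multi-state kinetics, which the recovery suite
  does not probe.
* GRO files carry 3-decimal nm coordinates, so cross-format agreement
  with PDB is limited to 5×10⁻³ Å by the format itself.
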