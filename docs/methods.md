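# Methods

This note documents the models and estimators implemented in `memorient`,
the defaults they use, and what the synthetic generator does and does not
emulate. Units throughout: nm, ns (μs for rates), degrees, kJ/mol, K;
k_B = 0.0083145 kJ mol⁻¹ K⁻¹ and the default temperature is 310 K (290 K
is the phase-separated-membrane option).

## Orientation order parameters

The membrane normal is fixed to the box +z axis (the bilayers analyzed are
planar; no local-normal estimation is attempted for undulating membranes).
The protein body axis **a** points from the COM of a base group to the COM
of a tip group; θt is the angle between **a** and +z. The body frame is
(e₁, e₂, e₃) with e₃ = **a** and e₁ the face vector orthogonalized against
**a**; θr = atan2(z·e₂, z·e₁) ∈ (−180°, 180°] is the azimuth of the
membrane normal in that frame (right-handed about **a**). When θt < 1°
the azimuth is degenerate and θr is reported as NaN. The convention is
configurable by swapping group definitions. All COMs use equal bead masses
(coarse-grained convention). Geometry is verified by a rigid fixture
generator that poses a toy G-domain at an exact (θt, θr) and recovers it to
1e-6°.

Contacts: a residue is in contact when any of its beads is within the
cutoff (default 0.55 nm, minimum image) of any bead of the lipid
selection; profiles are normalized by frame count. The partitioning
constant P_A = (C_A/n_A)/Σ_x(C_x/n_x) uses the time-averaged count C_A of
distinct lipids of species A within the cutoff of the probe; ΣP_A = 1 by
construction. The lateral RDF is two-dimensional (xy, minimum image), with
ideal-gas normalization at the target's lateral density; self-pairs are
excluded when reference and target coincide. Lateral MSD averages over all
time origins after unwrapping coordinates by half-box jump detection.

## Markov state model

The (θt, θr) space is discretized by k-means into 400 microstates.
Because θr is periodic, clustering operates on (θt, s·cos θr, s·sin θr)
with s = 180/π, which reproduces small periodic distances in degrees; θt
is left linear. k-means (k-means++ init, fixed seed) is fit on a random
subsample (200k frames by default; 50k in the recovery experiments) and
all frames are assigned to the nearest center — a standard cost control
that leaves assignment exact. Empty clusters are dropped with relabeling.

Transition counts use a sliding window at integer lag (maximal data use;
counts are correlated between overlapping windows, which matters for error
bars but not for the maximum-likelihood point estimate) and never cross
replica boundaries. Estimation is restricted to the largest strongly
connected component of the count graph (ergodic trimming). The reversible
maximum-likelihood transition matrix solves the detailed-balance-constrained
likelihood by the standard fixed-point iteration on symmetric fluxes,
x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j), to 1e-10 elementwise on T; its
stationary distribution is the normalized flux row sum. The estimator is
cross-checked in the tests against a generic constrained optimizer to 1e-6.

Implied timescales t_i = −τ/ln λ_i use the π-symmetrized spectrum
(eigvalsh on D^{1/2} T D^{-1/2}), after verifying detailed balance;
|λ| ≥ 1 maps to an infinite-timescale marker. The macrostate count M is
selected from the largest gap in the finite spectrum: with timescales
sorted descending and the stationary process counted as the first
(infinite) timescale, the largest ratio t_k/t_{k+1} after k resolved
timescales (those above the lag) gives M = k + 1. Ties break toward
smaller M; with nothing resolved above the lag, M = 1 with a warning. On
the 4-state synthetic system this selects M = 4 (three slow hidden
relaxations at 0.7–7.5 μs against a ~110 ns discretization-noise floor at
the 450 ns lag).

PCCA+ computes fuzzy memberships from the first M π-orthonormal right
eigenvectors via the inner-simplex vertex construction (successive
orthogonal deflation); barycentric coordinates are clipped of numerically
tiny negatives and row-renormalized. No subsequent objective refinement is
performed — on metastable matrices the vertex construction is already
essentially crisp, and the memberships only warm-start the HMM.

## Hidden Markov model

The M-state HMM treats PCCA macrostates as hidden states emitting k-means
microstates. Estimation is Baum–Welch on lag-subsampled label sequences:
every lag-th frame, with all offsets pooled as independent chains, so the
hidden transition matrix A is the macrostate transition probability at the
model lag (for frame-sampled continuous-time dynamics the subsampled
hidden chain is exactly Markov with A = exp(Qτ)). Initialization: A from
crisp-label transition counts at the lag, B from crisp per-macrostate
microstate histograms, both with a 1e-8 pseudocount (which also prevents
zero-probability lock-in throughout EM). The first ten iterations update
only B with A frozen — a generalized-EM warm-up, still monotone in
likelihood. The crisp warm start inflates the rare off-diagonal entries
of A through misclassified frames (basin-overlap frames register as
spurious transitions), and without the warm-up EM has to drift out of the
resulting shallow saddle, during which both the likelihood improvement
and the parameter motion are transiently tiny — any instantaneous
stopping rule can fire there and freeze a rare rate several-fold too
high. Sharpening B first removes the saddle. Convergence of the joint
phase then requires both the per-observed-frame log-likelihood
improvement below `tol` (default 1e-6; the multi-million-frame recovery
experiments use 3e-8 because the small off-diagonal entries refine in
increments below 1e-6/frame) and a stationary transition matrix
(max relative A change below 1e-3 per M-step).
Non-convergence warns and still returns the model with its trace. The
forward–backward pass has a numba-compiled kernel with a pure-numpy
fallback; both produce identical statistics (asserted in the tests), and
the implementation is cross-validated against hmmlearn on shared fixtures.

Populations are the left Perron eigenvector of A (reducible A is an
error listing the components). Rates: the default estimate is
K_ij = A_ij/τ for i ≠ j — transparent, and accurate when A_ij ≪ 1 — with
a generator-matrix estimate log(A)/τ behind `method="logm"` (falling back
with a warning when the logarithm is not a valid generator). For systems
where two slow states also exchange through fast intermediates, A_ij at a
long lag includes multi-step paths, so A_ij/τ systematically overestimates
the slow *direct* rates; the matrix-log estimate removes exactly this bias
and is the one quoted for the 4-state direct occluded↔exposed rates. For
the 2-state system there is no intermediate and A_ij/τ carries only the
first-order bias (1 − e^{−λτ})/λτ ≈ 3.5% at the default lag.

## Free-energy estimators

**Boltzmann FES.** F(bin) = −k_BT ln(H/H_max) on a 70×70 grid over
(θt, θr); the occupied minimum is zero by construction and empty bins are
flagged NaN, never imputed.

**WHAM.** Binned self-consistency on harmonic umbrella windows:
P_b ∝ Σ_i n_ib / Σ_i N_i exp[(f_i − U_i(b))/k_BT],
f_i = −k_BT ln Σ_b P_b exp(−U_i(b)/k_BT). Default bin width is one fifth
of the window spacing; bias energies are evaluated at bin midpoints.
Adjacent windows must share occupied bins (a gap is an error naming the
window pair). The fixed-point iteration converges geometrically with a
rate extremely close to 1 for ~100-window sets, so the per-iteration
offset change badly understates the distance to the solution; the default
stopping tolerance is therefore 1e-11 (≈7e4 iterations, a few seconds).
Block convergence splits each window's samples into three contiguous
blocks, runs WHAM per block, and reports the pointwise spread over bins
occupied in every block. Accuracy statements about recovered PMFs are
evaluated over the window-covered span: bins beyond the outermost centers
exist only through extreme-value tails of the outer windows and their
count grows with sample size without reflecting estimator quality.

**Umbrella sampler (generator).** Samples are drawn exactly from the
biased density exp(−(F(x) + k/2 (x−c)²)/k_BT) by inverse CDF on a fine
per-window grid (±8 thermal widths, 4000 points): trapezoidal CDF to
locate the interval, then closed-form inversion of the piecewise-linear
density within it. The residual discretization bias is O(h²) and
negligible against quadrature references.

**Well-tempered metadynamics.** The bias is a sum of deposited Gaussians;
each deposition has height W₀ exp(−V(s)/k_BΔT) with V the bias already
present at the deposition point, and γ = (T+ΔT)/T (γ = 15 ↔ ΔT = 4340 K at
310 K). Periodic CVs use the periodic displacement. The free-energy
estimate is the asymptotic relation F(s) = −γ/(γ−1) · V_G(s), min-shifted;
with no Gaussians the surface is flat zero. The toy validation couples the
bias to an overdamped Langevin particle (forces tabulated on a grid and
linearly interpolated; the bias table is refreshed at each deposition;
divergence beyond a configurable bound raises an error naming dt) on a
20 kJ/mol double well: 3×10⁵ steps at dt = 2e-4, friction 1, σ = 0.15,
W₀ = 1.5, deposition every 250 steps recover the barrier within a few
percent.

**PT-MetaD exchange.** Δ = (β_i − β_j)(U_i − U_j)
+ β_i[V_G^i(s_i) − V_G^i(s_j)] + β_j[V_G^j(s_j) − V_G^j(s_i)], acceptance
min(1, e^Δ). This satisfies detailed balance of the extended two-replica
ensemble in which each replica is Boltzmann-weighted with its own bias —
verified by a two-replica Monte-Carlo occupancy test and by hand-computed
exchange exponents.

## Synthetic generator: the study conditions

Kinetics are expressed in effective microseconds; no coarse-grained
time-scaling factor is applied, because the rates being emulated are
quoted directly in μs⁻¹. Macrostate dynamics are exact continuous-time
Markov jump processes (exponential waiting times, embedded-chain jumps),
frame-sampled at a 15 ns stride; replicas are independent and initialized
from the stationary distribution (the setting under which desk-scale
population recovery is well-posed).

Preset rate matrices are built from target stationary populations and
symmetric exchange coefficients c_ij via detailed balance
(k_ij = c_ij/π_i), with directly known rates overriding the constructed
edges:

* **Anionic GTP (4 states: transition-a, transition-b, occluded,
  exposed).** Stationary split 5/5/23/67%; the direct occluded→exposed
  and exposed→occluded rates are 0.0027 and 0.00096 μs⁻¹, and the
  exchange pathway through the membrane-detached transition-b state is
  30–400× faster edge-by-edge. The printed direct-rate pair is very
  slightly inconsistent with detailed balance against the printed
  populations (ratio 1.036); keeping the rates verbatim shifts the
  stationary split by <0.1% relative. Exchange coefficients are sized so
  every intermediate relaxes on the 1–2 μs scale, resolved above the
  450 ns lag (hidden timescales ≈ 13.6, 2.4, 1.2 μs).
* **POPC (2 states: non-specific, exposed).** Exposed occupies 91%; the
  exposed→non-specific rate is 0.0143 μs⁻¹ and the back rate
  (0.1446 μs⁻¹) follows from global balance.
* **Anionic GDP (4 states).** Occluded collapses to 1% and exposed rises
  to 87% (a ~20-point increase over GTP); the exposed→transition edges are
  slowed by roughly an order of magnitude relative to GTP.

Emissions are per-frame independent Gaussians around basin centers: the
exposed basin is centered at (75°, −90°) with σ = (22.5°, 35°) — a quarter
of the θt 30–120° / θr −160° to −20° basin extent — and the occluded basin
at (67.5°, 75°) with σ = (11.25°, 22.5°) for its 45–90° / 30–120° extent.
The two transition states sit in the remaining unspecific regions at
(20°, 60°) and (110°, 170°) with slightly tighter widths, chosen so that
basin overlap is moderate rather than degenerate. θr wraps to
(−180°, 180°]; θt reflects at 0°/180° (mass-preserving, no boundary
atoms).

**What the generator does not emulate.** Within-basin angle dynamics are
white (no intra-basin autocorrelation), so microstate discretization error
is milder than for real trajectories where slow intra-basin diffusion
contaminates the spectrum; basins are Gaussian rather than anharmonic;
the membrane is implicit (bead fixtures are rigid and flat, with no
undulations, so the COM-distance and contact analyses are validated on
constructed geometry, not emergent physics); and replica initialization
from the stationary distribution removes equilibration transients that
real simulations started from a detached pose must discard. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to real-data pathologies.

## Problem sizes and numerical choices

The recovery experiments use 50 ms aggregate effective time for the
4-state systems and 20 ms for the 2-state system (10 replicas at 15 ns
stride; 3.3M and 1.3M frames), k-means fit on a 50k-frame subsample,
and five independent seeds in the acceptance script; single runs complete
in about a minute on one CPU. Measured single-run scatter at this scale:
±1–2 percentage points on the major populations, ±0.05 points on the 1%
occluded population, a factor ≈1.5 on the slow 4-state direct rates and
≈15% on the POPC slow rate — the tolerances asserted in the acceptance
tests are set from this scatter. Degenerate inputs are handled explicitly:
absorbing states end jump simulation, identity transition matrices report
infinite timescales, reducible hidden chains raise with their components,
and empty FES bins stay NaN.

## Known limitations

* The θr convention matches the geometry it is defined with; published
  maps using a different body-frame convention differ by a θr offset or
  sign, so cross-study comparisons need a convention check.
* Rate error bars are not estimated (no Bayesian sampling; the
  bootstrap-over-replicas route is the recommended workaround).
* WHAM is one-dimensional and binned (no MBAR, no 2D WHAM).
* Metadynamics trajectories are not reweighted to unbiased ensembles; the
  FES comes only from the accumulated-bias relation.
* The MSM assumes the two angles are a sufficient reaction coordinate;
  no TICA/VAMP feature learning is provided.
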