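# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `braindyn`. The package implements a complete in-silico
version of a phase-coherence brain-state analysis pipeline: synthetic
cohort generation, LEiDA state extraction, whole-brain Stuart–Landau
(Hopf) modelling, effective-connectivity (EC) optimization with a
temporal-nonreversibility constraint, single-region perturbation scans,
and the covariate-adjusted statistical layer.

## LEiDA: phase-coherence states

Each subject's regional series is band-pass filtered to 0.01–0.08 Hz with
a second-order Butterworth applied forward–backward (`filtfilt`), the
de-facto choice for phase analyses because it is zero-phase. Per-region
means are removed; no volumes are trimmed after the Hilbert transform, so
the volume count is preserved and the edge bias of the analytic signal at
the first/last few volumes is accepted (it affects all subjects equally).
Whether to z-score before the Hilbert transform is an open choice; the
default is filter-only with mean removal.

At each volume the phase-coherence matrix is `cos(θ_i − θ_j)`. This
matrix is exactly rank 2 (`cosθ cosθᵀ + sinθ sinθᵀ`), so its leading
eigenvector is computed from a 2 × 2 Gram problem in O(N) per volume
rather than O(N³); the dense `eigh` path remains available and the two
are asserted equal in the tests. Eigenvector sign is normalized so that
the majority of components are negative (on an exact tie, the
largest-magnitude component is made negative), matching the convention
that the minority positive set marks the "active" community.

Clustering uses k-means with city-block distance: component-wise median
centroid updates (the L1 cost minimizer), k-means++-style seeding per
restart, at most 300 iterations with a 1e-6 cost tolerance, and the best
of `n_replicates` restarts (100 by default). An emptied cluster is
re-seeded at the point farthest from its nearest centroid, never dropped.
States are relabeled 1..K by descending occurrence probability on the
clustering input; assignment ties go to the lowest label. State labels
are 1-based throughout.

State–network correspondence is the Pearson correlation between the
rectified centroid (negative entries set to 0) and each functional
network's 0/1 region indicator, with Fisher-z 95% CIs; BH correction is
applied across networks per state by the caller.

## The Hopf whole-brain model

Each region is a Stuart–Landau oscillator near a supercritical Hopf
bifurcation, coupled diffusively through a non-negative matrix scaled by
a global coupling G; independent Gaussian noise of amplitude σ enters
both components. For an isolated noiseless region the stationary radius
is √a for a > 0 and 0 for a ≤ 0 — an analytic anchor the tests verify to
1%.

Numerical choices:

- **Integration** is Euler–Maruyama with dt = 0.1 s by default (stable for
  ω ≤ 2π·0.08 rad/s). The explicit scheme inflates the limit-cycle
  radius by ≈ ω²dt/2 (first order in dt); the radius-law tests therefore
  integrate at dt = 0.005 s, and a convergence test checks the observed
  order is ≥ 0.8.
- **Burn-in** defaults to 3000 s and is discarded; scaled-down runs use
  200 s, which the decay-time of the slowest mode (≈ 1/|2a| = 25 s at
  a = −0.02) comfortably allows.
- **Sampling** maps integration steps to volumes by subsampling every
  TR/dt steps (no averaging).
- **σ = 0.02** is the fitted-model default; the noise amplitude of any
  real cohort is unknown, so absolute fitted values should be read as
  conditional on this choice.
- Simulated series are band-pass filtered again before LEiDA stages,
  mirroring the empirical path.

Model fit is scored by a distance conventionally called Jensen–Shannon
in this literature, which is algebraically the *symmetrized
Kullback–Leibler (J) divergence* `0.5·[KL(p‖q) + KL(q‖p)]`, not the
mixture-based JSD. It is implemented exactly in that form, with
probabilities floored at 1e-12 and renormalized (the formula is undefined
at 0). The closed-form value `js((.75,.25),(.25,.75)) = ln(3)/2` pins the
implementation down. The G sweep covers 0–0.5 in steps of 0.01 (51
evaluations) by default and returns the argmin (ties to the smallest G).

`sweep_global_coupling` has two optional extensions beyond the plain
sweep, both defaulting to the plain behaviour: `n_reps` averages the
distance over independent noise realizations per grid point (the same
variance-reduction device the perturbation protocol uses), and `n_runs`
splits the simulated duration into independent runs whose state sequences
are pooled. The second matters for parameter recovery: a cohort is many
short sessions with independent transients, and comparing it against one
long continuous run introduces a small but systematic bias in the
recovered coupling. The recovery tests use both.

## Synthetic cohorts

The generator emulates the *derived* structure of a two-group
resting-state study: per-subject regions × volumes matrices (default
116 × 295 at TR = 2 s, though analyses here run at 20 regions), a
symmetric connectome, region metadata with left/right homolog pairs and
eight functional-network labels, covariates and severity indices. No
images, motion, or atlas geometry are simulated.

- **Connectome**: exponential distance decay on a ring embedding with
  lognormal weight jitter and random sparsification; homolog edges are
  never removed. This gives heavy-tailed, spatially structured weights
  without anatomical data.
- **Ground-truth dynamics**: all regions sit just past the oscillatory
  onset (a = +0.05) with intrinsic frequencies on a smooth 0.040–0.052 Hz
  gradient along the ring, σ = 0.01, and degree-normalized coupling
  (C/√(dᵢdⱼ), then max-0.2 rescale). As G grows, progressively longer
  arcs of the gradient phase-lock, so state occupancies change over the
  whole sweep range and identify the coupling. This regime was chosen
  deliberately: a homogeneous near-critical noise regime (a = −0.02
  everywhere) produces occupancy statistics that are nearly independent
  of G at 20 regions, leaving the coupling unidentifiable — unlike
  empirical cohorts, whose occupancy distributions are structured and
  coupling-sensitive. The degree normalization stabilizes the locking
  thresholds across connectome realizations.
- **Group contrast**: group B shares the connectome but has higher global
  coupling (0.24 vs 0.16) and one network's bifurcation parameters raised
  by 0.06. At 15+15 subjects the full pipeline (LEiDA → MANCOVA) detects
  this contrast in ~80% of replicate cohorts.
- **Covariates**: age ~ U(18, 50), sex ~ Bernoulli(0.84) (the emulated
  cohorts are 84% male), education ~ U(6, 20) years, mean framewise
  displacement ~ half-normal(0.1) + 0.02 mm. No missing values.
- **Severity indices** are rank-noisy monotone functions of each
  subject's mean Kuramoto order parameter (global phase synchrony),
  targeting Spearman ρ ≈ 0.4. The order parameter is used rather than a
  state probability because state probabilities only exist after
  clustering; global synchrony is a monotone proxy for the occupancy of
  the globally synchronized state, so the Spearman-partial pipeline has a
  recoverable target without circularity.

What passing tests on these cohorts do **not** show: robustness to head
motion, physiological noise, hemodynamic convolution, inter-subject
anatomical variability, or site effects — none of which are modelled.

## EC optimization and nonreversibility

Pairwise Pearson FC is mapped to `FS = −½·ln(1 − FC²)` (clipped at
|FC| = 0.9999) so the optimizer handles non-negative quantities.
Time-shifted correlations at lag τ (default 2 s = 1 volume at TR 2 s) are
computed forward and on the order-flipped series; for finite samples the
reversal matrix equals the transposed forward matrix, making
`FS_diff = FS_forward − FS_reversal` exactly antisymmetric with zero
diagonal — the discrete arrow-of-time measure.

The update is
`G_ij ← G_ij + ε·(FS_emp − FS_mod)_ij − ε′·(FS_diff_emp − FS_diff_mod)_ij`
on masked entries (existing structural connections plus both directions
of every homolog pair), with negatives clipped to 0 and the matrix
renormalized to max 0.2 each iteration. Defaults ε = 0.001, ε′ = 0.002;
the scaled-down experiments use larger steps (0.01) to converge in tens
of iterations. Each iteration simulates one noise realization with an
iteration-indexed seed (`n_sims_per_iter` can average several).
Convergence: the *running best* of the combined objective (1 − corr_FS,
plus 1 − corr_FSdiff in combined mode) must improve by < 1e-3 over a
5-iteration window, capped at 200 iterations; tracking the running best
rather than the raw per-iteration value keeps single noisy iterations
from triggering a premature stop. With `tol = inf` the loop performs exactly one update
beyond initialization, which the tests pin down.

Node summaries: total information flow `Σⱼ G_ij + Σⱼ G_ji` and asymmetry
`Σⱼ |G_ij − G_ji|` (a normalized variant is exposed; the per-node L1 form
is the adopted definition).

Two properties of this system informed the test design and are worth
recording. First, with identical frequencies and symmetric coupling the
fully synchronized zero-lag state solves the dynamics for *any* coupling
asymmetry, so directedness leaves no trace on lagged statistics in the
locked regime — directed ground truths for recovery experiments must be
run in the noise-driven regime (a < 0), where coupling transmits
fluctuations with a lag. Second, heterogeneous *symmetric* coupling also
produces nonzero FS_diff (exchange symmetry between i and j is broken by
the graph even without directed edges); the ordering experiments
therefore plant asymmetry that preserves the symmetric envelope
(`g_ij = c_ij(1+u)`, `g_ji = c_ij(1−u)`) on a circulant base with
identical frequencies, so the planted direction is the sole source of
systematic nonreversibility. In that design the FS-only mode's FS_diff
fit correlation fluctuates around zero while the combined mode's is
higher in the large majority of seeds, and only the combined mode
produces asymmetric EC at all — the orderings the acceptance suite
asserts.

## Perturbation protocol

A perturbation adds Δa to one region's bifurcation parameter. Default
strength grids follow the two transition directions: −0.15…0.2 toward
the disordered regime and −0.3…0.05 toward the healthy one, both in
steps of 0.01 (36 values), 10 repetitions per cell. Per-cell seeds derive
from `SeedSequence([master, region, strength_index, rep])`, so scans are
reproducible and cells independent. The per-cell score is the mean of
per-repetition distances (the repetition values are retained for the
benchmark's paired test); pooling the PMS before scoring is a
defensible alternative — the mean of per-repetition distances was
adopted because it preserves variance information. Failed cells are
marked invalid and excluded from the selection base.

Selection takes the `ceil(fraction × valid cells)` smallest mean
distances (0.5% of a 116 × 36 grid is ceil(20.88) = 21), ties broken by
(region, strength). Each selected cell is compared against the same
region's strength-0 repetitions with a paired t-test. The homolog
asymmetry is the mean over pairs and strengths of |J-S(left) −
J-S(right)|.

Scaled-down scans (fewer regions, coarser strength grids, shorter
durations, fewer repetitions) are a first-class configuration path; the
self-target sanity experiment (target = the model's own long-run PMS)
runs 20 regions × 7 strengths × 5 reps at 1500 s per cell and finds the
optimum within ±0.02 of zero strength for the majority of regions.

## Statistical layer

- **MANCOVA**: one state probability is dropped (the sum-to-one
  constraint makes the K-th redundant; Wilks' Λ is provably invariant to
  which — asserted in tests), and the model
  `intercept + group + age + sex + education + meanFD` is fitted to the
  K−1 responses. For the single-df group factor the exact-F transform of
  Wilks' Λ applies: `F = ((1−Λ)/Λ)·((vₑ−p+1)/p)` with df `(p, vₑ−p+1)`,
  `vₑ = n − rank(X)`; at n = 88, K = 3, four covariates this is (2, 81).
  The implementation matches `statsmodels` MANOVA to 1e-8 and its type-I
  error is 4–5% over 500 null draws. Covariates constant in a sample
  (e.g. single-sex subsets) are dropped before fitting.
- **ANCOVA** post hocs: nested-model F with df (1, n − rank), BH-corrected
  across states.
- **BH-FDR** wraps the standard step-up procedure (statsmodels) and is
  oracle-tested against a hand-rolled implementation.
- **Spearman partial correlation**: rank-transform x and y, residualize
  both on the (raw) covariates by least squares, Pearson-correlate the
  residuals; p from the t approximation with df = n − 2 − #covariates;
  percentile bootstrap CI over subject resampling (1000 replicates).
  Note `pingouin` ranks the covariates as well; the two coincide when
  fed ranked covariates, which a test exploits as an independent check.
- **Paired t**: two-sided; identical inputs return (t = 0, p = 1);
  zero-variance differences with nonzero mean raise (t undefined).
- α = 0.05 two-sided throughout.

## Problem sizes used in tests and analyses

The full-scale protocol (116 regions, 88 subjects, 51-point sweep,
cohort-length simulations, 36 × 116 × 10 perturbation cells) is
faithfully parameterized but quadratically expensive; the shipped
analyses and tests run the same code at sizes chosen to finish on a
single CPU: 20-region cohorts, 10–45 subjects per group, 150–295
volumes, sweeps over 0.08–0.24, 24–50 optimizer iterations, and scans of
7–15 strengths × 3–5 repetitions. All scale parameters are ordinary
function arguments, so full-scale runs are a matter of compute, not
code.

## Known limitations

- No hemodynamic forward model (Balloon–Windkessel) and no regional
  heterogeneity beyond a and ω.
- The Euler–Maruyama scheme is first-order; its radius bias is
  documented above and material only when dt is coarse relative to ω.
- Perturbations are single-region and constant in time.
- The synthetic severity indices are planted against global synchrony,
  so they validate the statistical machinery, not any clinical claim.
- K selection ("smallest K with significant group differences") is an
  orchestration choice left to the analysis scripts; the library treats
  K as a parameter.
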