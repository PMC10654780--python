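# Methods

## Model

The decoder is a penalized least-squares classifier on extracted features:
given N trials with features X ∈ ℝ^{N×P} and labels y ∈ {−1,+1}^N, it
minimizes (1/2)‖y − Xw‖² + λP(w) and predicts sign(Xw). Treating ±1 labels
as a regression target makes the fidelity term differentiable with
Lipschitz gradient, so a proximal-gradient (ISTA-type) scheme applies to
any penalty whose proximity operator is computable:

* gradient step through the intermediate point
  v = w − (1/β) Xᵀ(Xw − y), with fixed step 1/β, β = ‖XᵀX‖₂
  (computed by power iteration to relative tolerance 1e−8);
* shrinkage step w ← prox_{P/β}(v).

There is no intercept; instead features are z-scored with training-set
statistics, which centers the decision score so sign(Xw) is meaningful.
Initialization is w⁰ = 0; iteration stops when the relative iterate change
drops below 1e−6 or after 1 000 iterations (both configurable). No
backtracking or momentum is used: the fixed 1/β step keeps the convex
families monotone in objective and converges rapidly for the strongly
thresholding non-convex families.

## Penalties and proximity operators

All six families share the `PenaltySpec` container (family, λ, shape γ,
group map, inter-group weight):

| family | penalty (per coordinate / block) | shape default |
|---|---|---|
| l1 | λ\|w\| | — |
| group | λ √\|g\| ‖w_g‖₂ | — |
| sparse_group | λ‖w‖₁ + λ_g Σ √\|g\| ‖w_g‖₂ | λ_g = 2⁻¹ |
| scad | linear→quadratic taper→plateau (γ+1)λ²/2 | γ = 3 (needs γ > 2) |
| mcp | λ\|w\| − w²/(2γ), plateau γλ²/2 past γλ | γ = 2 (needs γ > 1) |
| cauchy | λ log((γ² + w²)/γ) | γ = 0.007 (subject-dependent); 0.003 for pooled cross-subject decoding |

Scalar proxes: L1 is the soft threshold. SCAD and MCP use their piecewise
stationary points *evaluated against the scalar objective per branch* —
candidates are the clipped stationary point of each branch plus 0 and the
breakpoints — which stays exact in the degenerate regimes (SCAD
γ ≤ 1 + 1/β, MCP βγ ≤ 1) where the scalar problem is non-convex or flat.
Equal-height minima break toward the smaller magnitude (the sparser
solution). The group prox is the blockwise soft threshold with block
weight λ√|g|/β; the sparse-group prox composes the elementwise soft
threshold first (the exact prox of the summed penalty). Default groups
are one per time-frequency unit (two CSP features).

The Cauchy prox minimizes (β/2)(w−v)² + λ log((γ²+w²)/γ) per coordinate.
Its stationarity condition is the cubic w³ − vw² + (γ² + 2λ/β)w − vγ² = 0,
solved by Cardano's formula. With a negative discriminant — the common
case at γ = 0.007 — all three real roots are computed trigonometrically
and the global minimizer of the scalar objective is selected explicitly;
no complex arithmetic is truncated. Note the gradient of the penalty
enters the cubic as 2λ/β (dividing, not multiplying, by the step scale);
the brute-force oracle in the test suite confirms this form. Every prox
family is validated against dense-grid + golden-section one-dimensional
minimization to 1e−4 across a (v, λ, β) grid.

Two structural facts about the Cauchy prox shape its use in the pipeline:

* It behaves like a hard threshold: below a λ/β-dependent jump the global
  minimizer is a near-zero root, above it a barely-shrunk root. Retained
  coefficients are therefore shrunk *relatively less* than the soft
  threshold's λ/|v| — the near-unbiasedness that motivates the penalty —
  but only above the jump; just above the selection boundary the prox
  discards rather than biases.
* The near-zero root is never exactly zero (the cubic's constant term is
  −vγ² ≠ 0); deselected coordinates land at O(γ²) remnants. The decoding
  model therefore zeroes Cauchy coefficients with |w| ≤ γ — the penalty's
  own scale, below which it is locally quadratic (ridge-like) and the
  coordinate carries no selected signal. Without this rule the large-λ
  limit degenerates to a dense matched filter w ∝ Xᵀy instead of the
  empty model. The solver itself never snaps, so fixed-point and oracle
  properties hold exactly; only the stored model and CV fold evaluation
  apply the rule. The other five families produce exact zeros and pass
  through unchanged.

## Feature extraction

Trials are cut into 2 s windows stepped by 0.5 s (5 windows on a 4 s
trial; the enumerated windows 0–2, 0.5–2.5, …, 2–4 s force the step
reading of the overlap), each window is band-pass filtered into 4 Hz-wide
bands stepped by 2 Hz over 4–40 Hz (17 bands), and CSP is fitted per
(window, band) unit: per-trial covariances are trace-normalized, averaged
per class into C₊ and C₋, and the generalized eigenproblem
C₊u = μ(C₊+C₋)u is solved; the eigenvectors with largest and smallest μ
form the unit's filter pair (m = 1 pair by default). Features are
log(varⱼ/Σₖvarₖ) over the pair — the standard log-variance CSP
convention. Filtering is a 6th-order Butterworth (3 biquad sections)
applied forward–backward (zero phase, reflection padding), appropriate
for offline decoding. Windowing precedes filtering; edge effects on 2 s
segments at the lowest band are accepted as part of the design. If a
class covariance is rank-deficient, shrinkage toward the scaled identity
is escalated (α = 10⁻⁶, 10⁻³, 10⁻¹) before failing. CSP is fitted on
training trials only and reused across CV folds; the standardizer is
refit per fold. Test trials never influence filters (checked by a
permutation leakage guard).

## Model selection and evaluation

λ is selected by stratified, seeded 10-fold CV over the 51-point grid
{2^e : e = −5, −4.8, …, 5}, warm-starting the solver along the descending
grid within each fold; the λ with the best mean fold accuracy wins, ties
toward the largest λ (sparsest model). "10 cross-validations" is read as
one 10-fold CV. Subject-dependent evaluation trains one model per subject
on its train split; subject-independent evaluation pools all non-target
subjects' train+test trials and scores the target's test split.
Prediction ties (score exactly 0) resolve to +1.

Baselines: two-class Fisher score (μ₊−μ₋)²/(σ₊²+σ₋²) and equal-width
10-bin histogram mutual information (bits), each ranked per CV fold and
combined with an FLDA classifier (pooled-covariance direction
Σ⁻¹(μ₊−μ₋), midpoint threshold, small identity shrinkage); the prefix
size k is chosen over {1…30} ∪ {40, 60, …, P}, ties toward the smallest k.

## Synthetic data

`make_regression` draws standard-normal columns, k coefficients of
magnitude `effect` with random signs, and labels y = sign(Xw + σε) — a
classification bench whose true support and coefficients are known.
Because labels are thresholded, even an oracle estimator recovers an
attenuated multiple of w_true; the bias comparison between penalties is
therefore relative, which is exactly what the support-recovery study
measures.

`make_eeg` emulates the event-related (de)synchronization mechanism:
sources are band-pass-filtered white noise (variance, not phase, carries
class information), one source per designated time-frequency unit has its
variance multiplied by `effect` for class +1 inside the unit's window
only, and channels−1 background rhythm sources are class-independent.
Sources are mixed to sensors by a random unit-norm mixing matrix, and 1/f
background noise (FFT-shaped, std 0.5) plus white sensor noise (std 0.1)
are added. Defaults: 8 channels, 250 Hz, 4 s trials, unit (1–3 s,
10–14 Hz), balanced interleaved labels. Amplitude constants were chosen
once so the effect=3 bench is decodable (≥ 0.9) and weaker effects are
not saturated. What this generator does *not* emulate: volume-conduction
head geometry, artifacts (EOG/EMG), non-stationarity across a session,
and inter-subject variability beyond a fresh mixing matrix per seed —
so passing benches demonstrate the pipeline's statistical mechanics, not
performance on real EEG.

## Numerical choices and edge cases

* Power iteration for β: relative tolerance 1e−8, seeded start, null-space
  restart; all-zero X is rejected.
* Window/band enumeration uses a 1e−9 arithmetic guard so 0.5 s steps do
  not drop the final window to floating-point error.
* Division-free guards: zero-variance CSP projections and zero-power
  segments raise; standardizer maps zero-variance columns to scale 1.
* Prox ties (non-convex equal-height minima) return the smaller-magnitude
  root; prox(−v) = −prox(v) holds to machine precision.
* Penalty values may be negative for Cauchy with γ < 1 (offset λP log γ);
  only differences from P(0) are meaningful, and P(w) − P(0) ≥ 0.
* Solver divergence (non-finite objective) raises with the iteration and
  penalty configuration; CLI maps all errors to non-zero exit codes.

## Problem sizes in the standard studies

The support-recovery study uses 50 replicates of N=100, P=170, k=6,
effect 1.0, σ=1, with λ chosen per method by 5-fold CV over every 4th
grid exponent (13 values) and the model refit on all rows. The end-to-end
benches use 200 trials (100 train / 100 test) at effect 3 (easy) and
effect 1 (null control), full 51-point 10-fold CV. The γ-sweep and
convergence-trace experiments run on 120-trial cohorts and seeded
100×170 regression problems respectively.

## Known limitations

* The fixed-step solver is first-order; badly conditioned feature
  matrices converge slowly (tens of thousands of iterations for tight
  tolerances on underdetermined LASSO problems). ADMM or accelerated
  variants are deliberately out of scope.
* The Cauchy support rule |w| > γ ties feature selection to the penalty
  scale; with γ far from the coefficient scale of standardized features
  it may over- or under-select.
* CV reuses the full-training-set CSP, which inflates fold accuracies in
  absolute terms; it is used only to *rank* λ values, and the reported
  test accuracies come from truly held-out trials.
* GDF/EDF/BrainVision readers are not included; adapt external data by
  constructing `EEGTrialSet` (or the manifest container) directly.
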