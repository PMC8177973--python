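# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `semgsel`.

## Feature extraction

Each analysis window of length L yields, per channel, the ordered feature
vector (WL, IAV, RMS, SSI, Kurtosis, Skewness, ZC, AR1..AR4):

* WL = Σ|x_{i+1} − x_i|, IAV = Σ|x_i|, RMS = √(Σx²/L), SSI = Σx².
* Kurtosis = [Σ(x−x̄)⁴/(L−1)]/SD⁴ − 3 and
  Skewness = [Σ(x−x̄)³/(L−1)]/SD³, with the *sample* SD (divisor L−1) to
  match the L−1 divisor of the moment sums.  A zero-variance window makes
  these undefined; the default policy drops the window with a logged
  warning (configurable to raise or to keep NaN sentinels).
* ZC counts adjacent pairs with x_i·x_{i+1} < 0 **and** |x_i − x_{i+1}| >
  T; default T = 10 signal units.
* AR coefficients a₁..a₄ of x_i = Σ_p a_p x_{i−p} + ε_i, estimated by
  least squares (covariance method: the normal equations of the 4-lag
  linear predictor), with a pseudo-inverse fallback for singular windows.

Window length and overlap are conventions, not reproductions: 200 samples
with 50% overlap, typical for myoelectric control at 1 kHz.  Per-sample
labels become window labels by majority vote, ties going to the
first-occurring class; windows never straddle trial (segment) boundaries,
and windows covering a label transition can optionally be discarded.

## MTSR (ℓ2,1-penalised multitask regression)

Objective: ½‖Y − WᵀX‖²_F + λΣᵢ‖wⁱ‖₂ with one-hot Y (each column sums
to 1; classes ordered by sorted label).  X is the row-standardized
feature matrix (z-scored per variable) by default; standardization of the
inputs is configurable.

Solver: iteratively reweighted least squares.  Stationarity of the
objective gives (XXᵀ + λD)W = XYᵀ with D_ii = 1/‖wⁱ‖₂; we use the
smooth surrogate D_ii = 1/√(‖wⁱ‖² + ε²), which is a
majorize–minimize step and therefore monotonically decreases the
ε-smoothed objective (asserted to 1e−9 per step in the tests).  Cold
start is the ridge solution; ε = 1e−8, relative-objective tolerance
1e−7, max 200 iterations (non-convergence returns the best iterate
flagged, never raises).  An accelerated proximal-gradient (FISTA) solver
with exact row-wise soft-thresholding is kept as an independent
reference; the two agree to better than 1e−4 relative objective on
randomized instances.

Selection: a row survives if its norm exceeds `zero_tol` (1e−6) times
the largest row norm **and** an absolute floor.  The floor is needed
because ε-smoothed IRLS never yields exact zeros: converged truly-zero
rows linger at ≈ ε·λ_max/λ (λ_max = max row norm of XYᵀ, the smallest
penalty at which W = 0 is stationary), and rows still shrinking when the
objective test fires are bounded through the per-step decrease, giving
floor = max(10·ε·λ_max/λ, 30·tol·J_final/λ).  At λ = 0 no floor applies
(the ridge solution has no zero rows).

The penalty sweep reports (λ, selection size, CV accuracy) per grid
point.  Selection size is *expected* to shrink with λ but IRLS
thresholding can break strict monotonicity; violations are logged, not
asserted.  `pick_lambda` operationalizes the usual eyeballed
accuracy-versus-size trade-off as: the smallest selection (largest λ on
ties) whose accuracy is within a margin (default 1 percentage point) of
the best.

## mRMR

Mutual information uses the plug-in estimator on discretized states, in
bits; 0·log 0 cells contribute nothing.  Default discretization is the
classic 3-state coding per variable: thresholds at mean ± 0.5·SD (sample
SD), states −1/0/+1; equal-frequency binning is available.  Zero-variance
variables map to the single state 0.

The greedy search seeds with the most relevant variable and then
maximizes I(x_j; c) − (1/|S|)Σ_{x_i∈S} I(x_j; x_i) (difference form,
default) or the quotient form with the mean redundancy clipped at 1e−12.
Exact score ties break to the lower variable index for determinism.  The
number of kept variables m defaults to the MTSR selection size so that
both screenings feed the fusion with equally sized sets.

## Co-occurrence, ranking and fusion

For a selected variable set, counts[i][j] is the number of features
channels i and j both use (diagonal stored 0).  Channels are ranked by
row sum with competition ranking (tied channels share the best rank of
their block).  Fusion strategies:

* `mutual_top` (default): find the smallest depth t at which the two
  top-t lists share ≥ k channels; keep the k intersection members with
  the smallest rank-sum, ties broken by smaller combined row sum, then
  channel position.  Chosen because it reproduces all three published
  fused subsets (k = 2, 3, 4) from the published per-method orderings.
* `rank_sum` (Borda): k smallest rank-sums directly, same tie-breaks.
  Transparent but reproduces only the k = 2 and k = 3 published subsets;
  at k = 4 it promotes a high-rank-sum-tie channel instead of the
  published fourth channel.  Kept as an option for exactly that reason.

Channels selected at k are *not* guaranteed to be a subset of those at
k+1 under `mutual_top`; this is inherent to intersection growth and is
deliberately not asserted.

The majority feature rule keeps features used by strictly more than C/2
channels (">4" of 8), per method, plus the union across methods.

## Evaluation

SVM with RBF kernel (C = 1, γ = 1/(p·Var(X)), scikit-learn's `scale`),
stratified 5-fold CV with shuffling under a fixed seed, scaler fit on
training folds only.  Precision/recall are computed per class from
one-vs-rest confusion counts and macro-averaged; undefined ratios (empty
denominator) are reported as 0 with an explicit flag.  Folds pool all
windows; this is optimistic relative to leave-subject-out protocols and
is documented as such.  A class with fewer members than folds raises
with guidance to reduce the fold count.

## Synthetic generator

Per trial of gesture class g, channel c carries
gain(g,c)·AR(4)-colored Gaussian noise + unit white noise.  The AR
shaping (1.456, −1.17, 0.524, −0.2916) places poles at 0.9·e^{±0.2πi}
and 0.6·e^{±0.5πi} — a broad low-frequency resonance — and is validated
for stability at configuration time.  Informative channels get
class-dependent gains from a deterministic cyclic pattern in
(1, 1+strength]; all other channels stay at gain 1.  Defaults: 8
channels, 7 classes, 1 kHz, 2 s trials, 30 trials per class, three
informative channels at strength 3 — small enough for minutes-scale runs
while matching the canonical channel/gesture counts.

The generator emulates only the amplitude/variance structure that the
time-domain features measure.  It does **not** model motor-unit action
potentials, electrode crosstalk, spectral differences between gestures,
non-stationarity within a trial, or inter-subject variability.  Passing
tests on this harness therefore demonstrate the pipeline's correctness
and its ability to recover amplitude-informative channels, not
performance on physiological recordings.

A structural limitation worth knowing: co-occurrence ranking scores a
channel by the features it *shares* with other channels.  With a single
informative channel the sparse screening concentrates on that channel
alone, all off-diagonal counts vanish and the ranking degenerates —
the statistic presumes several informative channels with overlapping
feature types (as in the reference tables).  The test suite covers the
single-channel case through selection counts instead, and the fused
recovery property on the three-planted-channel default.

## Problem sizes and determinism

All randomness funnels through explicit seeds (generator configs, CV
fold assignment, pipeline config).  Reruns of a pipeline config produce
byte-identical artifacts; the manifest (config, config hash, versions,
seed) suffices to reproduce a run.  The heavier statistical checks use
20 seeded replicates of the default generator conditions (≈ 4000
windows each) for end-to-end recovery, 20 randomized instances
(d ≤ 20, n ≤ 60, c ≤ 4) for solver agreement, and d ≤ 8 instances for
brute-force mRMR equivalence — sizes chosen to make the statistical
assertions stable while keeping a full run in the minutes range.

## Known limitations

* The bundled reference selections are inputs (verbatim encodings of the
  published tables), not recomputations from raw recordings; the original
  8-channel dataset is not redistributed, so dataset-dependent accuracy
  figures are out of scope.
* The MI estimator, discretization, λ/threshold that produced the
  published 36-variable selections are unknown; exact replication of
  those selections from raw signals is therefore not promised.
* One cell of the published mRMR co-occurrence table contradicts its own
  Sum row and its mirror cell; the encoding uses the symmetric,
  Sum-consistent value (see `semgsel/fixtures.py`).
* Pooled-window CV overestimates inter-subject generalization.
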