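# Methods

## Model and assumptions

The package addresses binary screening on severely imbalanced tabular
data: one row per subject, a mixed panel of continuous measurements and
binary indicators, labels y ∈ {0, 1} with class 1 (cases, set P) far
rarer than class 0 (controls, set N). Three assumptions shape the design:

* missing data is handled by row deletion before any modelling (one
  subject = one complete row);
* the minority class is the clinically important one, so sensitivity is
  the primary metric and specificity a constraint, not a target;
* no single feature separates the classes — per-feature standardized mean
  differences are small and class distributions overlap heavily, so the
  signal is only available multivariately.

## Feature selection

Two screens run independently over the candidate features and the union
of their survivors is kept.

**Significance screen (F_s).** Binary indicators: Pearson chi-square on
the 2×2 feature-by-label table, *without* continuity correction —
χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), p from χ²(1). The
no-correction form is the one that reproduces the published per-feature
statistics from their printed counts (e.g. 30.985 for chest pain). A zero
margin yields statistic 0, p = 1 and a degenerate flag. Continuous
features: pooled-variance Student's t from per-class summaries
(n, mean, SD); the pooled (not Welch) form again matches the published
values (19.14 vs printed 19.12 for neutrophil count; Welch would give
≈ 16.4).

**Logistic screen (F_l).** One multivariable logistic model containing
all candidates, fitted by unpenalized maximum likelihood (IRLS via
statsmodels GLM, intercept included, 100 iterations cap). Per-coefficient
Wald z = B/SE, two-sided p, OR = exp(B), 95% CI = exp(B ± 1.96·SE).
Quasi-separation (a zero cell of a binary feature against the label, or a
runaway Wald SE > 50) sets a flag instead of raising; flagged features
stay in the F_l decision with their Wald p as computed. This screen is
deliberately distinct from any *classifier* logistic baseline: it is the
SPSS-style unpenalized analysis model, not an L2-penalized predictor.

**Union rule.** F_s = {p ≤ α}, F_l = {Wald p ≤ α}, F_set = F_s ∪ F_l with
α = 0.05 by default. The threshold is inclusive (≤, not <). No
multiple-testing correction is applied: the screens are a permissive
pre-filter, not an inference procedure.

## Cost-sensitive SVM base learner

The weak learner minimizes the class-weighted soft-margin objective

    Σ_i c_i [1 − y_i f(x_i)]_+ + λ‖f‖²,  c_i = w1 (x_i ∈ P) / w2 (x_i ∈ N)

with λ = 1/(2C); the production path is the C-parameterized dual solver
(scikit-learn SVC with per-class weights, which enforces the box
constraints 0 ≤ α_i ≤ C·c_i), while the penalty-form objective is kept as
an independent test oracle for linear kernels. Defaults follow the
screening-model setting: RBF kernel, C = 4, γ = 0.004, w1 = 1.3, w2 = 1.

Numerical choices:

* **Standardization.** Features are z-scored inside `train`, fitted on
  the training data only. With γ = 0.004 on raw clinical units the RBF
  kernel would be dominated by the largest-scale features; z-scoring
  makes γ meaningful and predictions invariant to feature rescaling.
* **Decision threshold.** predict(x) = 1 iff f(x) ≥ 0. The exact-zero tie
  goes to the positive class: in screening, a borderline case should be
  flagged.
* **Weight grid.** The cost-sensitivity study uses
  {(1,1), (1.3,1), (1.6,1), (2,1)}; weights above 2 on the positive class
  are excluded because specificity drops below a usable range. All grid
  settings share identical CV folds and identical per-fold undersampling
  draws, so the comparison isolates the weight effect.

## Underbagging ensemble

T = ⌊|N| / |P|⌋ (65 at the motivating cohort's 802/52,411). The majority
indices are shuffled once by a seeded generator and cut into T
consecutive blocks of size |P|; the |N| mod |P| remainder (281 at cohort
scale) is discarded with a logged count. The stated partition constraints
(disjoint blocks of size |P| whose union is N) cannot all hold when |P|
does not divide |N|; discarding the remainder is the minimal reading of
undersampling and is what the implementation does. Each balanced set
D_i = N_i ∪ P trains one weak learner; aggregation is a hard-label
majority vote (decision-value averaging is available behind a flag), with
the even-T tie resolved positive. Training order is irrelevant to the
result. Inside cross-validation, T is recomputed from each training
split, never from the full dataset.

## Evaluation protocol

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); a zero denominator is
reported as NaN with a warning. Cross-validation uses **stratified**
k-fold splits (k = 7 by default) with shuffling: with a 65:1 ratio,
unstratified folds can starve a test fold of positives, so stratification
is a deliberate clarification of "partitioned evenly". Reports carry
per-fold Se/Sp rows, the fold mean, and the across-fold sample variance
(n−1 denominator, displayed ×10⁻³). Model factories receive only the
training split plus a fold seed, so any undersampling or partitioning is
confined to training data. Fold assignments and fold seeds depend only on
(seed, k), making multi-model comparisons paired. Comparator algorithms
(boosting variants, random forests, nearest neighbours, ...) are reached
only through the same generic factory interface; their internals are out
of scope.

## Synthetic cohort generator

The real cohort is unavailable, so `synthetic` generates tables that
emulate its regime: configurable class counts (default 120 vs 7,800 =
65:1, a scaled-down cohort that keeps test runtimes in seconds),
16 continuous features as class-conditional unit-variance Gaussians and
8 binary features as class-conditional Bernoullis, half of them
informative. Continuous effect sizes are drawn once per seed from
U(0.1, 0.6) SD — the weak single-feature separability regime — and binary
probability gaps from U(0.05, 0.15) over a control base rate of 0.3,
matching the small case/control frequency gaps typical of clinical
indicator variables. Features are independent by default (an optional
equicorrelation parameter adds a shared Gaussian factor); all randomness
flows from one root generator, so identical spec + seed reproduces tables
bit-identically.

What the generator does *not* emulate: real marginal shapes (skewness,
units, outliers), realistic feature correlation structure, measurement
error, or missingness (rows are complete unless requested otherwise).
Tests passing on this benchmark therefore demonstrate the *mechanics* of
the method — weight monotonicity, ensemble gains, variance reduction —
under a controlled overlap regime, not clinical performance on any real
population.

A fixed 12-row, 3-feature worked example (9 controls, 3 cases, so T = 3
with an exact partition) is hard-coded for unit tests and documentation.

## Benchmark problem sizes

The behavioral studies run at n_pos = 120 / n_neg = 7,800 with seven-fold
CV: each training split holds ~103 positives, giving T ≈ 64 weak learners
per split, each trained on ~206 balanced samples. The bagging
variance-reduction study repeats the paired ensemble-vs-single-SVM
comparison over ten CV seeds. These sizes were chosen so the entire suite
runs in a couple of minutes on one core while keeping the 65:1 ratio of
the motivating application.

## Known limitations

* Published fold tables contain two "Average" cells that do not equal the
  mean of their printed fold values (the weighted-SVM (1.3,1) specificity
  and the EasyEnsemble sensitivity; a third, the ensemble specificity,
  differs in the last printed digit). The reproduction checks exclude
  them and a dedicated test documents the mismatch. Likewise, published
  across-fold variance rows are not recoverable from the printed fold
  values under either the n or the n−1 convention, so variance is
  reported but never checked against published values.
* Multi-level categorical features are rejected rather than one-hot
  encoded; the motivating panel's categoricals are binary.
* No probability calibration, ROC analysis, or training-time
  benchmarking; hard labels and Se/Sp are the whole evaluation surface.
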