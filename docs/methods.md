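# Methods

This note documents the models, numerical choices and limitations behind
`fallfs`: what the synthetic cohort generator simulates, how each analysis
stage is defined, and which design points were genuinely open and how they
were settled.

## The synthetic cohort model

Real cohorts of this kind (instrumented gait analysis plus questionnaires in
a Multiple Sclerosis clinic) are not publicly deposited, so every downstream
stage is exercised on synthetic cohorts with the same statistical skeleton.

**Latent structure.** Each subject carries a single latent severity
`s ~ N(0, 1)`. The binary faller label is `y ~ Bernoulli(sigmoid(a + b·s))`
with slope `b = 1.5`; the intercept `a` is solved by Gauss–Hermite
quadrature and bracketed root finding so the *marginal* prevalence equals the
requested value (default 0.139, i.e. 172/1240). A single-factor model is the
simplest structure under which filter methods can provably separate
informative from noise features; it does not attempt to model distinct
balance/gait/cognition factors.

**Features.** The nine physical blocks follow the clinical battery: Basic
(two timed walking tests + the nine EDSS features), two pressure-mat gait
blocks (82 features each, normal and dual-task walking), two wearable gait
blocks (84 each), two postural-sway blocks (32 each), MSWS-12 (12 five-level
Likert items) and EMIQ (9 four-level Likert items). The EDSS data set is a
9-column view of Basic; the All data set concatenates the nine physical
blocks (428 columns). An informative feature with loading `λ` is
`λ·s + e`, `e ~ N(0, 1)`; ordinal features cut the same latent at
equiprobable thresholds of its marginal `N(0, 1 + λ²)` into the declared
level count (codes 1..L). Non-informative features are pure noise.

By default exactly nine questionnaire items are informative (three EMIQ,
six MSWS-12) with `λ = 1.2`. The slope `b = 1.5` is fixed and `λ` was chosen
once so that a Gaussian naive Bayes on the nine planted items scores in the
F1 0.4–0.6 band at default scale — a realism calibration of the generator's
conditions, not a fitted quantity. A consequence of planting signal only in
the questionnaires is that the rater-based EDSS features carry no fall
signal in the default cohort, unlike real MS cohorts where EDSS is strongly
fall-associated; pass a custom `informative_features` map to change that.

**EDSS total.** The total score is a deterministic monotone surrogate of the
eight functional scores: `total = max(f) + 0.5 · max(0, #{f ≥ 2} − 1)`.
This is *not* the clinical Neurostatus algorithm (rater-administered and out
of scope); it exists so that knowledge-based imputation has a rule it can
invert, and the same function is used by generator and imputer.

**Missingness.** Per block, two mechanisms apply: a
missing-completely-at-random cell rate (system errors; default 1–2%) and a
severity-linked term `clip(sigmoid(slope·s) − ½, 0, 0.99)` that removes the
subject's *entire* block — an assessment the patient could not complete.
The `−½` centering makes `slope = 0` reduce exactly to MCAR. Sensor blocks
default to `slope = 0.75`, questionnaires and the rater block to 0, so
severe subjects lose whole sensor recordings and each data set keeps its own
complete-case n (the concatenated data set retains roughly 920–940 of 1240
subjects at defaults). Severity-linked missingness is deliberately *not*
cell-wise: cell-wise MAR plus median imputation would write severity
information into every noise feature and invert the benefit of feature
selection.

## Preprocessing

Metric features are imputed with the reference-row median (even counts: mean
of the central pair); ordinal features with the mode, ties broken toward the
smaller code. The EDSS total is recomputed from complete functional scores
by the surrogate rule; a missing functional score with an observed total
takes the mode of that score among reference subjects at the same total;
remaining holes fall back to the plain mode. All features — ordinals are
treated as quasi-metric, since the items have a natural order — are z-scored
with reference-row mean/SD; constant features are dropped with a warning.

Statistics are always fitted on reference rows and applied unchanged
elsewhere, so both validation designs are supported: `fit_scope: global`
(fit on all rows before cross-validation — the default, matching the most
literal reading of the original protocol, which acknowledges its optimistic
bias) and `fit_scope: per_fold` (leakage-free refitting inside every
training fold), with `nested: true` additionally re-running feature
selection per fold.

## Filter rankers

Chi-square, information gain and MRMR operate on discretized data: ordinal
features at their native codes, metric features cut into at most 10
equal-frequency bins (duplicate quantile edges collapse, so low-cardinality
features keep their natural levels). Equal-frequency binning is robust to
the heavy skew of gait variability measures; the bin count is exposed.

* **Chi-square** — Pearson `Σ(O−E)²/E` on the feature-level × label table,
  no continuity correction; degenerate tables score 0 rather than raising.
* **Information gain** — `H(y) − H(y|X)` in bits (plug-in estimates).
* **MRMR** — greedy forward ordering; the first feature maximizes `I(X;y)`,
  each next maximizes `I(X;y) − mean_{s∈S} I(X;X_s)` (the
  mean-difference/MID form; the quotient form is behind a flag). The
  recorded score is the greedy objective at selection time, so the score
  sequence is not monotone.
* **ReliefF** — exhaustive probes by default; per probe, the k = 10 nearest
  hits and misses under Manhattan distance on range-normalized features;
  each weight accumulates mean miss-difference minus mean hit-difference,
  divided by the probe count. Classes smaller than k+1 reduce k with a
  warning. Sub-sampled probes are drawn without replacement from the seed.

Score ties anywhere break by feature-name lexicographic order (logged), so
every ranking is a deterministic permutation of the input features.

## Ensemble calculus

The top `m = max(1, round_half_away_from_zero(threshold·p))` features of
each ranking form the filter subset (`m = p` at threshold 1.0, the
no-selection baseline; the rounding rule is compatible with every subset
size derivable from the protocol and is flagged for sensitivity analysis).
Combination is membership counting: union ≥ 1, union 2 ≥ 2, union 3 ≥ 3,
intersection = 4; hence union ⊇ union2 ⊇ union3 ⊇ intersection on every
input. Empty results (possible with disjoint rankings at tight thresholds)
are flagged infeasible and skipped by the grid runner rather than raised.
Final subsets are ordered by descending membership count, then name.

## Evaluation

Grids: decision tree — criterion {gini, entropy} × depth 2..10 × minimum
leaf size 5..30; kNN — weights {uniform, distance} × metric {euclidean,
manhattan} × k 2..10; SVM (RBF) — C {0.1, 1, 10, 100} × γ {1e−5 … 1};
Gaussian naive Bayes has no tuned parameters. Grid search scores each
candidate by mean fold F1 on one stratified 5-fold split shared by all
candidates; ties keep the earlier candidate in a simplest-first enumeration
(shallower/larger-leaf trees; larger-k, uniform, euclidean kNN; smaller C
then γ SVMs).

Repeated CV draws a fresh stratified fold assignment per repetition
(`seed + r`), pools the out-of-fold predictions within a repetition, scores
the pooled vector once, and reports mean ± sample SD over repetitions —
consistent with the very small SDs such protocols report. Undefined ratios
(zero denominators) are returned as 0 with a warning; κ uses
`(p_o − p_e)/(1 − p_e)`.

The permutation test shuffles labels uniformly per permutation, re-runs the
scalar evaluator (mean F1), and applies the add-one rule. Hyperparameters
chosen on the observed labels are reused across permutations — re-tuning
1000 times is computationally disproportionate and the null being tested is
the feature–label dependency, not the tuning procedure.

## Orchestration

The grid runner evaluates every (data set × model × threshold ×
combination) cell; a subject missing an entire constituent block is dropped
from that data set's analysis only, which is what gives each data set its
own n. The per-data-set winner maximizes mean F1; exact ties go to fewer
selected features, then to the family order GNB, DT, kNN, SVM, then to
higher threshold/combination name. Defaults are reduced-scale
(3 repetitions, 99 permutations); full-scale values (10/1000) are plain
arguments.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence tests run at ≤ 40 samples × ≤ 6 features against
brute-force reimplementations (1e−9 agreement). Calibration of the
permutation null uses 50 cohorts of n = 250 with a 10-feature
label-independent block at 200 permutations, compared against the 99%
binomial interval around the attainable level `⌊α(B+1)⌋/(B+1)`.
Planted-feature recovery runs 20 default cohorts (n = 1240, 428 features);
the acceptance script uses 5 cohort replicates and 199 permutations. These
sizes are the package's desk-scale defaults; all of them scale up by
argument.

## What passing tests do and do not show

The generator reproduces the *structure* that makes this analysis hard —
block widths, mixed scales, rare positives, redundancy through a shared
latent, severity-linked loss of whole assessments — and the pipeline's
qualitative headline on it matches the clinical finding: strict
ensemble selection concentrates on the informative questionnaire items and
beats the all-feature baseline. It does not emulate real gait physiology
(no distinct balance/speed factors, no measurement autocorrelation, no
informative EDSS by default, Gaussian marginals for metric features), so
absolute metric values on synthetic cohorts are not predictions of clinical
performance, and the original study's numeric tables are not reproducible
without its patient data.

Known limitations: the EDSS surrogate rule is a stand-in; the discretization
used by the original two software environments is unknown, so their exact
rankings are not reproducible; complete-case handling per data set is an
inference from the protocol's differing n; and the global fit scope
intentionally reproduces a validation design that is optimistic relative to
per-fold refitting.
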