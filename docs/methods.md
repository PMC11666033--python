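# Methods

## The question and the measurement

A binary classifier scored on samples with different positive-class
fractions φ can receive very different metric values even when nothing
about the model changes, because most confusion-matrix metrics depend on
φ through the class-size weights in their denominators. The package
operationalizes "consistency" of a metric as the variance, across
datasets that differ only in prevalence, of (a) the metric's value for a
fixed model and (b) the rank the metric assigns that model within a
candidate set. A metric is consistent if both variances are small.

## Metric algebra

Every single-threshold metric is implemented twice, in algebraically
identical forms: from the counts (TP, FN, TN, FP) and from the rate
quadruple (n, φ, TPR, TNR). The equivalence is a tested invariant
(agreement within 1e-10 on random matrices), which guards each
parameterization against transcription errors in the other. Two choices
deserve note:

- **Cohen's kappa** uses the expected accuracy
  `((TP+FN)(TP+FP) + (TN+FP)(TN+FN)) / n²`, equivalently
  `φ²·TPR + φ(1−φ)(2−TPR−TNR) + (1−φ)²·TNR` in rate form. These two
  expressions are exactly equal; the rate form carries no residual 1/n
  factor.
- **Fβ** is the standard `(1+β²)·PPV·TPR / (β²·PPV + TPR)` with β ∈
  {0.5, 2} in the default catalogue. The shipped reference table's F-beta
  rows are *not* reproducible from their confusion counts with this (or
  any standard) formula; they are retained in the fixtures tagged
  `known_discrepant` and excluded from exact oracles.

Zero-denominator cases (PPV with nothing predicted positive, DOR at a
degenerate threshold, MCC with an empty margin) return a tagged
`UNDEFINED` value rather than NaN or ±inf. Aggregators skip such cells
and log the exclusion count; nothing is imputed. This matters at the
threshold grid's extremes, where PPV/NPV and DOR blow up by construction.

AUC is the normalized Mann–Whitney statistic computed from average score
ranks, crediting ties ½ — the probability that a random positive case
outranks a random negative one. It is checked against brute-force pair
enumeration and the trapezoidal ROC area.

**Thresholding rule.** Predicted-positive iff score ≥ t (configurable to
strict >). With ≥, a score of exactly 0.5 is classified positive at the
0.5 cutoff and t = 0 labels everything positive, making the degenerate
grid endpoints well defined.

## The prevalence sweep

Each sweep step removes k uniformly sampled members of the shrinking
class (without replacement) and adds k members of the growing class
sampled *with replacement*, so n never changes and the class counts
follow the exact schedule pos₀ ± k·i regardless of the random stream.
Defaults (k = 30, 76 downward + 79 upward iterations → 156 datasets)
span φ ≈ 0.08–0.83 from a balanced start of (2775, 3439).

Added rows are drawn from the *original* dataset's class pool by default
rather than the current iterate's, limiting duplication cascades late in
an arm; the `current` mode is also implemented. Arms chain cumulatively
(dataset i+1 derives from dataset i). Stopping is by fixed iteration
count; an adaptive TPR/TNR-saturation stop was considered and rejected
as a default because it makes the dataset count a random variable.

`correlation_drift` verifies the design's premise: the max absolute
change of any pairwise correlation (features plus outcome,
integer-coded categoricals) stays small across the series — median below
0.03 on default synthetic sweeps, asserted < 0.1 in tests.

## Models and the evaluation grid

Five scikit-learn families (GLM, RF, KNN, LDA, GBM) are fit inside a
preprocessing pipeline (one-hot categoricals; standardized numerics for
the scale-sensitive GLM/LDA/KNN), with hyperparameters chosen by k-fold
cross-validated AUC over deliberately small grids — the study's claims
concern metric behavior, not tuning. The random forest uses a leaf-size
floor of 20 so its probability estimates stay smooth at these sample
sizes. Each sweep dataset is split 80/20 with its own seed derived from
the global split seed.

The random-guess baseline assigns exactly `round(φ_test·n)` positive
labels by random permutation, scoring positives uniform on [0.51, 0.99]
and negatives on [0.01, 0.49], so thresholding at 0.5 recovers the
assignment. Its expected accuracy is φ² + (1−φ)², and its chance-
corrected metrics (BI, MCC, kappa) center at zero — both tested.

Confusion metrics are evaluated at the 0.5 cutoff; AUC uses the full
ranking. Ranks use average tie-breaking with UNDEFINED entries ranked
last; rank rows always sum to m(m+1)/2. All variances are sample (n−1)
variances.

## Variance-homogeneity tests

Metrics are grouped into prevalence-*sensitive* (the three F-scores,
Jaccard, TPR, TNR, Fowlkes–Mallows) and -*insensitive* (the remaining
study metrics); both sets are overridable. Bartlett and Levene run on
the metric-type × model interaction cells. The F-test compares the
pooled within-cell variances of the two groups: each cell is
mean-centered first, because the quantity of interest is dispersion
*across prevalence*, not level differences between models — without
centering, a rank table's pooled variance is dominated by the spread of
mean ranks across models and the test is structurally powerless.
Zero-variance cells are excluded from Bartlett (which cannot handle
them) and flagged.

## Threshold analysis

Thresholds are ordered by distance from 0.5 (0.5 first; distance ties
broken toward the smaller threshold). The default `unique-scores` mode
uses the distinct predicted scores; when the pooled candidate set
exceeds 1,500 it is thinned to evenly spaced quantiles (keeping 0.5),
preserving the all-thresholds span at bounded memory — the study scale
of interest is ~1,200 thresholds, one per distinct test-set score. A
`uniform-grid` mode covers models emitting few distinct scores.

Confusion counts at all thresholds are computed by sorted-score
bisection and metrics evaluated vectorized; agreement with the scalar
path is a tested invariant. Incremental averaging takes, per dataset,
the mean metric over each threshold prefix (skipping UNDEFINED cells),
then the variance of those means across datasets; at prefix size 1 this
reproduces the single-threshold variances exactly, and AUC curves are
flat by construction. `ols_slope` regresses variance on the number of
thresholds (statsmodels OLS, two-sided slope p-value).

## Synthetic data generator

The generator emulates a seven-feature recidivism sample: gender
~ Bernoulli(0.81), age ~ truncated normal (34 ± 11, ≥ 18 years), three
zero-inflated Poisson criminal-history counts (zero-heavy, as such
counts are), crime degree ~ Bernoulli(0.65) and a four-level charge
category. The outcome is Bernoulli(logistic(β₀ + Σβ·x)); β₀ is found by
root-finding on a large fixed-seed feature sample so the population
prevalence hits the target (default 0.452, default n = 6214). Default
effect sizes are a calibration choice: they place a tuned logistic
model's held-out AUC in the low-0.7 range, the moderate-signal regime
the reference analysis operates in.

What the generator does *not* emulate: the real data's feature
correlations (features are drawn independently), non-logistic structure
(the true model is linear in the features, so the linear families are
not handicapped as they may be on real data), and measurement artifacts.
Passing stochastic tests therefore shows that the *pipeline* reproduces
the qualitative findings in a controlled regime, not that those findings
hold for any particular real dataset.

## Problem sizes used in tests

The stochastic end-to-end checks run a scaled-down study chosen as a
faithful miniature of the full design: n = 3,000; k = 70 with 16
iterations per arm (33 datasets spanning φ ≈ 0.09–0.83, mirroring the
full span); 3-fold CV; all six models and 18 metrics; ~1,500 thresholds.
On this configuration AUC attains the smallest mean ranking variance,
all variance-homogeneity tests reject, ~92 of 108 (metric, model)
threshold slopes are negative and significant, and AUC slopes are zero
to machine precision. The full-scale configuration (156 datasets,
n = 6,214, 10-fold CV) is the package default for `run_study`.

## Known limitations

- When model families are nearly tied in true performance, every
  metric's ranking variance contains tie noise; conclusions about
  *relative* consistency are robust to this, absolute variances are not.
- DOR is unbounded; in pooled-value variance comparisons its scale can
  dominate the insensitive group. The tests are two-sided, so this
  affects interpretation of direction, not significance.
- The variance-homogeneity F-test's cell-centering loses a handful of
  degrees of freedom per cell that the pooled ddof=1 estimate ignores;
  with hundreds of observations per group the effect is negligible.
- KNN emits few distinct probability values; with `unique-scores`
  thresholds its grid rows change in steps. Use `uniform-grid` if this
  matters.
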