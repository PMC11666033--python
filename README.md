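# prevmetrics

Tools for studying how *consistently* binary-classification evaluation
metrics rate and rank models as the prevalence of the positive class
changes, while sample size and the relationships among variables are held
constant.

Evaluation metrics are routinely compared on a single dataset, but in
applied settings — clinical screening, risk scoring, recidivism
prediction — the same model is re-evaluated on samples whose positive-case
fraction φ drifts over time. Many popular metrics track φ almost
monotonically, so their values (and the model rankings they induce) change
even when the model does not. `prevmetrics` implements the full analysis
pipeline for quantifying this effect across 18 confusion-matrix metrics
and the rank-based AUC, five model families (logistic regression, random
forest, k-nearest neighbors, linear discriminant analysis, gradient
boosting) and a prevalence-matched random-guess baseline.

## What is inside

- **Metric algebra** (`prevmetrics.confusion`): the 2×2 confusion matrix,
  a catalogue of metrics in two exactly equivalent parameterizations —
  raw counts (TP, FN, TN, FP) and the rate quadruple (n, φ, TPR, TNR) —
  with tagged `UNDEFINED` handling for vanishing denominators, and AUC as
  the normalized Mann–Whitney statistic

  MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
  AUC = P(score⁺ > score⁻) + ½·P(score⁺ = score⁻).

- **Prevalence sweep** (`prevmetrics.sweep`): the constant-n rebalancing
  simulation — each iteration drops k random cases of one class and adds
  k resampled cases of the other, so the positive count follows the exact
  schedule pos₀ ± k·i while pairwise correlations stay approximately
  fixed. The default schedule (k = 30, 76 downward and 79 upward
  iterations) produces 156 datasets spanning φ ≈ 0.08–0.83.

- **Consistency analysis** (`prevmetrics.consistency`): the evaluation
  grid over (dataset, model, metric), average-tie model ranking, the
  variance of values and ranks across prevalence, and F/Bartlett/Levene
  tests of variance homogeneity between prevalence-sensitive and
  -insensitive metric groups.

- **Threshold analysis** (`prevmetrics.thresholds`): metric values over
  all decision thresholds ordered outward from 0.5, incremental
  threshold-averaging curves, and OLS regressions of variance on the
  number of thresholds used.

- **Synthetic data** (`prevmetrics.synthetic`): a generator for
  recidivism-style tabular data (seven mixed-type features, logistic
  outcome, intercept calibrated to a target prevalence, default
  n = 6214 at φ = 0.452), plus small worked-example fixtures.

- **Study driver** (`prevmetrics.study`, CLI `prevmetrics`): one call /
  command runs the whole pipeline from a YAML config and serializes every
  table as CSV plus a JSON summary and manifest.

## Worked example

```bash
python examples/metric_algebra.py
```

```
confusion matrix: tp=2 fn=2 tn=5 fp=1
accuracy = 0.70
MCC      = 0.36
rates form: n=10 phi=0.40 TPR=0.50 TNR=0.83
MCC from rates = 0.36  (identical)
rank AUC = 0.750
ROC area = 0.750  (equal by construction)
```

Seventy percent of the ten cases are classified correctly, yet the
Matthews correlation is only 0.36: MCC, being the Pearson correlation of
the true and predicted label vectors, rewards alignment on *both* classes
and is far harsher than accuracy. The same value falls out of the
(n, φ, TPR, TNR) parameterization, and the rank AUC coincides with the
trapezoidal area under the ROC polygon.

The other scripts in `examples/` each demonstrate one capability:
`prevalence_sweep.py` (constant-n rebalancing and correlation drift),
`model_consistency.py` (ranking variance and the homogeneity tests),
`threshold_analysis.py` (incremental threshold averaging and slopes) and
`full_study.py` (the end-to-end driver). A scaled-down full study runs in
a couple of minutes; on the study-scale configuration (156 datasets,
n = 6214, six models) expect hours on one CPU.

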