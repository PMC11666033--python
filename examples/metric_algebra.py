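"""Metric algebra on a worked example: counts, rates and rank AUC.

Builds the confusion matrix of a 10-case prediction, evaluates MCC and
accuracy, shows the equivalent (n, prevalence, TPR, TNR) parameterization,
and computes the rank-based AUC of a small scored prediction set.
"""

import numpy as np

from prevmetrics import (ScoredPredictions, auc_rank, confusion_from_labels,
                         metric_from_confusion, metric_from_rates, roc_points)

true_labels = (1, 0, 0, 0, 0, 1, 1, 0, 0, 1)
predicted = (0, 0, 1, 0, 0, 0, 1, 0, 0, 1)

cm = confusion_from_labels(true_labels, predicted)
print(f"confusion matrix: tp={cm.tp} fn={cm.fn} tn={cm.tn} fp={cm.fp}")
print(f"accuracy = {metric_from_confusion('accuracy', cm).unwrap():.2f}")
print(f"MCC      = {metric_from_confusion('MCC', cm).unwrap():.2f}")
# 70% of cases are classified correctly, yet MCC is only 0.36: the
# correlation view punishes misaligned positives much harder than accuracy.

rp = cm.to_rates()
print(f"rates form: n={rp.n} phi={rp.phi:.2f} TPR={rp.tpr:.2f} TNR={rp.tnr:.2f}")
print(f"MCC from rates = {metric_from_rates('MCC', rp).unwrap():.2f}  (identical)")

preds = ScoredPredictions(labels=np.array([1, 0, 1, 0, 0]),
                          scores=np.array([0.7, 0.6, 0.5, 0.5, 0.1]))
print(f"rank AUC = {auc_rank(preds):.3f}")
pts = roc_points(preds)
print(f"ROC area = {np.trapezoid(pts[:, 1], pts[:, 0]):.3f}  (equal by construction)")
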