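"""The evaluation metrics on a tiny hand-checkable example.

Four samples, two of each class. The confusion matrix counts the four
outcomes; precision/recall/F1 are percentages; the ROC curve sweeps the
distinct scores as thresholds and AUC is its trapezoidal area, which equals
the fraction of (positive, negative) pairs ranked correctly (ties half).
"""

from molgcn import auc, confusion, evaluate, f_measure, roc_curve

labels = [1, 0, 1, 0]
predicted = [1, 1, 0, 0]
scores = [0.9, 0.8, 0.7, 0.1]

cm = confusion(labels, predicted)
print(f"TP={cm.TP} FP={cm.FP} TN={cm.TN} FN={cm.FN}")

report = evaluate(labels, predicted, scores)
print(f"precision: {report.precision:.2f}%   recall: {report.recall:.2f}%"
      f"   F1: {report.f1:.2f}%")
print(f"FPR: {report.fpr:.2f}   TPR: {report.tpr:.2f}")

roc = roc_curve(labels, scores)
print(f"ROC points: {[(round(x, 2), round(y, 2)) for x, y in roc.points]}")
print(f"AUC: {auc(roc):.2f}  (3 of 4 positive/negative pairs correctly ranked)")

print(f"F2 (recall-weighted): {f_measure(report.precision, report.recall, alpha=2):.2f}%")
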