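"""Compute the full confusion-matrix metric bundle.

Builds a 3-class prediction fixture with a known 10% corruption rate and
reports the macro-averaged one-vs-rest metrics: accuracy, sensitivity
(TPR), specificity (TNR), precision (PPV), NPV, F1, misclassification rate
and Matthews correlation coefficient.
"""

import numpy as np

from antcad import confusion, macro_metrics, make_confusion_fixture

rng = np.random.default_rng(0)
y_true, y_pred = make_confusion_fixture(n_classes=3, n=600, error_rate=0.1, rng=rng)
report = macro_metrics(confusion(y_true, y_pred, 3))

print("confusion matrix (rows = true, cols = predicted):")
print(report.confusion.counts)
print(f"\nACC {report.acc:.4f}   MR {report.mr:.4f}   (always sum to 1)")
print(f"TPR {report.tpr:.4f}   TNR {report.tnr:.4f}   PPV {report.ppv:.4f}   NPV {report.npv:.4f}")
print(f"F1  {report.f1:.4f}   MCC {report.mcc:.4f}")
print("\n-> with 10% of predictions corrupted, accuracy lands near 0.9 and the")
print("   MCC near 0.85: a balanced summary robust to class imbalance.")
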