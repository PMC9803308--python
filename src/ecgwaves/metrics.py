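"""Per-class and aggregate evaluation of the delineation labels.

All metrics are one-vs-rest over the five classes (P, QRS, T, ISO, PAD):
for class c, TP/FP/FN/TN are taken from the 5x5 confusion matrix and
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision = TP/(TP+FP),
accuracy = (TP+TN)/total, F1 = harmonic mean of precision and sensitivity.
The "average" row is the unweighted mean over the five classes. Undefined
ratios (zero denominators) are reported as NaN, never silently as 0.

ROC and precision-recall curves are one-vs-rest threshold sweeps on the
per-sample class probabilities; ROC AUC uses trapezoidal integration and
PR AUC uses step-wise interpolation (average precision). Micro and macro
averages over the present classes are both reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import sklearn.metrics as _skm

from .synthetic import CLASS_NAMES

__all__ = [
    "confusion",
    "per_class_metrics",
    "roc_pr_curves",
    "per_sample_accuracy",
]

N_CLASSES = len(CLASS_NAMES)


def confusion(true_labels, predicted_labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return _skm.confusion_matrix(t, p, labels=np.arange(n_classes))


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-rest accuracy/sensitivity/specificity/precision/F1 per class.

    Index: class names plus an unweighted ``average`` row. Zero-denominator
    ratios come out as NaN (and propagate into the average).
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be >= 0")
    n = cm.shape[0]
    total = cm.sum()
    names = list(CLASS_NAMES[:n]) if n <= N_CLASSES else [str(i) for i in range(n)]
    rows = {}
    for c in range(n):
        tp = cm[c, c]
        fn = cm[c, :].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        prec = _ratio(tp, tp + fp)
        acc = _ratio(tp + tn, total)
        f1 = _ratio(2 * prec * sens, prec + sens) if np.isfinite(prec) and \
            np.isfinite(sens) else float("nan")
        rows[names[c]] = {"accuracy": acc, "sensitivity": sens,
                          "specificity": spec, "precision": prec, "f1": f1}
    df = pd.DataFrame(rows).T
    df.loc["average"] = df.mean(axis=0, skipna=False)
    return df


def _ratio(num, den) -> float:
    return float(num / den) if den > 0 else float("nan")


def roc_pr_curves(true_labels, probabilities) -> dict:
    """One-vs-rest ROC and PR curves with areas, per class + averages.

    ``true_labels``: integer labels (any shape) or one-hot (n, n_classes);
    ``probabilities``: matching (n, n_classes) scores with rows summing to 1.
    Returns ``{class_name: {fpr, tpr, auc_roc, precision, recall, auc_pr}}``
    plus ``macro``/``micro`` average AUC entries. A class absent from the
    truth gets ``None`` curves and NaN areas.
    """
    probs = np.asarray(probabilities, dtype=float)
    probs = probs.reshape(-1, probs.shape[-1])
    n_classes = probs.shape[1]
    y = np.asarray(true_labels)
    if y.ndim >= 2 and y.shape[-1] == n_classes and y.max() <= 1:
        onehot = y.reshape(-1, n_classes).astype(int)
    else:
        onehot = np.eye(n_classes, dtype=int)[y.ravel()]
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    out = {}
    roc_aucs, pr_aucs = [], []
    for c in range(n_classes):
        name = CLASS_NAMES[c] if c < N_CLASSES else str(c)
        truth = onehot[:, c]
        if truth.sum() == 0 or truth.sum() == len(truth):
            out[name] = {"fpr": None, "tpr": None, "auc_roc": float("nan"),
                         "precision": None, "recall": None,
                         "auc_pr": float("nan")}
            continue
        fpr, tpr, _ = _skm.roc_curve(truth, probs[:, c])
        prec, rec, _ = _skm.precision_recall_curve(truth, probs[:, c])
        out[name] = {
            "fpr": fpr, "tpr": tpr, "auc_roc": float(_skm.auc(fpr, tpr)),
            "precision": prec, "recall": rec,
            "auc_pr": float(_skm.average_precision_score(truth, probs[:, c])),
        }
        roc_aucs.append(out[name]["auc_roc"])
        pr_aucs.append(out[name]["auc_pr"])
    flat_truth = onehot.ravel()
    flat_probs = probs.ravel()
    out["macro"] = {"auc_roc": float(np.mean(roc_aucs)) if roc_aucs else float("nan"),
                    "auc_pr": float(np.mean(pr_aucs)) if pr_aucs else float("nan")}
    out["micro"] = {
        "auc_roc": float(_skm.roc_auc_score(flat_truth, flat_probs)),
        "auc_pr": float(_skm.average_precision_score(flat_truth, flat_probs)),
    }
    return out


def per_sample_accuracy(true_labels, predicted_labels, mask=None) -> float:
    """Fraction of positions labeled correctly (optionally over a mask)."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    if mask is not None:
        m = np.asarray(mask).ravel().astype(bool)
        t, p = t[m], p[m]
    if len(t) == 0:
        return float("nan")
    return float(np.mean(t == p))
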