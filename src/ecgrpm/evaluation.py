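"""Multiclass evaluation: confusion matrix, one-vs-rest rate metrics,
micro/macro ROC curves with AUC.

Per class, the one-vs-rest contingency gives

    ACC = (TP + TN) / (TP + TN + FP + FN)    PPV = TP / (TP + FP)
    SE  = TP / (TP + FN)                     SP  = TN / (TN + FP)
    F1  = 2 * PPV * SE / (PPV + SE)

The overall accuracy is trace / total. "Average" PPV/SE/SP are macro
(unweighted) means over classes. ROC curves sweep thresholds over the
predicted scores; the micro curve pools all (sample, class) decisions,
the macro curve averages per-class curves on a common FPR grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapz_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    class_order: tuple[str, ...]
    accuracy: float                       # trace / total
    per_class: dict[str, dict[str, float]]   # ACC/PPV/SE/SP/F1 per class
    macro: dict[str, float]               # unweighted means of PPV/SE/SP/F1
    roc: dict = field(default_factory=dict)   # curves + AUCs, when scores given

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        path.write_text(json.dumps(clean({
            "class_order": list(self.class_order), "accuracy": self.accuracy,
            "per_class": self.per_class, "macro": self.macro, "roc": self.roc,
        }), indent=2))
        return path


def confusion(y_true, y_pred, class_order) -> ConfusionMatrix:
    """Count matrix: entry (i, j) is #samples of true class i predicted j."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    order = tuple(class_order)
    index = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} "
                             f"not in class_order {order}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=order)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s: division by zero, reporting 0", what)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest rates per class plus overall accuracy and macro means."""
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    total = cm.total
    per_class: dict[str, dict[str, float]] = {}
    for i, name in enumerate(cm.class_order):
        tp = int(c[i, i])
        fp = int(c[:, i].sum() - tp)
        fn = int(c[i, :].sum() - tp)
        tn = total - tp - fp - fn
        ppv = _safe_div(tp, tp + fp, f"PPV[{name}]")
        se = _safe_div(tp, tp + fn, f"SE[{name}]")
        sp = _safe_div(tn, tn + fp, f"SP[{name}]")
        f1 = _safe_div(2 * ppv * se, ppv + se, f"F1[{name}]")
        per_class[name] = {
            "ACC": (tp + tn) / total, "PPV": ppv, "SE": se, "SP": sp, "F1": f1,
        }
    macro = {key: float(np.mean([per_class[n][key] for n in cm.class_order]))
             for key in ("PPV", "SE", "SP", "F1")}
    return EvalReport(
        class_order=cm.class_order,
        accuracy=float(np.trace(c) / total),
        per_class=per_class, macro=macro,
    )


def roc(y_true, scores, class_order) -> dict:
    """One-vs-rest, micro- and macro-averaged ROC curves with AUC.

    ``scores`` is an (n, K) array of per-class scores (rows ~ sum to 1).
    Classes absent from ``y_true`` are skipped in the macro average with
    a warning. AUC uses the trapezoidal rule.
    """
    y_true = np.asarray(list(y_true))
    scores = np.asarray(scores, dtype=float)
    order = tuple(class_order)
    if scores.shape != (len(y_true), len(order)):
        raise ValueError(f"scores must be {(len(y_true), len(order))}, "
                         f"got {scores.shape}")
    onehot = np.stack([(y_true == c).astype(int) for c in order], axis=1)

    per_class: dict[str, dict] = {}
    present: list[str] = []
    for j, name in enumerate(order):
        if onehot[:, j].sum() == 0:
            logger.warning("class %s absent from y_true: skipped in macro ROC",
                           name)
            continue
        fpr, tpr, _ = _sk_roc_curve(onehot[:, j], scores[:, j])
        per_class[name] = {"fpr": fpr, "tpr": tpr,
                           "auc": float(_trapz_auc(fpr, tpr))}
        present.append(name)

    fpr_mi, tpr_mi, _ = _sk_roc_curve(onehot.ravel(), scores.ravel())
    micro = {"fpr": fpr_mi, "tpr": tpr_mi,
             "auc": float(_trapz_auc(fpr_mi, tpr_mi))}

    grid = np.unique(np.concatenate([per_class[n]["fpr"] for n in present]))
    mean_tpr = np.zeros_like(grid)
    for n in present:
        mean_tpr += np.interp(grid, per_class[n]["fpr"], per_class[n]["tpr"])
    mean_tpr /= len(present)
    macro = {"fpr": grid, "tpr": mean_tpr,
             "auc": float(_trapz_auc(grid, mean_tpr))}

    return {"per_class": per_class, "micro": micro, "macro": macro}


def evaluate(y_true, y_pred, class_order, scores=None) -> EvalReport:
    """Full report: confusion-derived rates plus ROC when scores are given."""
    report = metrics(confusion(y_true, y_pred, class_order))
    if scores is not None:
        report.roc = roc(y_true, scores, class_order)
    return report
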