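"""Confusion-matrix metrics and the Evalue aggregate over repeated runs.

Cohen's kappa K = (Po - Pe)/(1 - Pe) corrects observed agreement Po for the
chance agreement Pe implied by the marginals; balanced accuracy is the mean
of per-class recalls, so each class weighs equally however small.  The
composite model-selection score over r repeated runs,

    Evalue = -100 * mean(kappa) * mean(BA) * ln(sd(kappa) * sd(BA)),

rewards models whose repeated cross-platform performance is both high on
average and stable (sample SD, ddof=1; the SD product is clamped at 1e-12 so
degenerate zero-spread runs stay finite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score as _sk_auc

from crossnorm.core_io import DataError

EVALUE_EPS = 1e-12


@dataclass
class ConfusionMatrix:
    """n x n counts, rows = true class, columns = predicted, in class_order."""

    class_order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.class_order)
        if self.counts.shape != (n, n):
            raise DataError(f"confusion matrix must be {n}x{n}, got {self.counts.shape}")
        if (self.counts < 0).any() or self.counts.sum() < 1:
            raise DataError("confusion matrix needs nonnegative counts with total >= 1")

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_order) -> "ConfusionMatrix":
        counts = _sk_confusion(y_true, y_pred, labels=list(class_order))
        return cls(tuple(class_order), counts)


def kappa(c: ConfusionMatrix) -> float:
    """Cohen's kappa from the confusion matrix; Pe = 1 degenerates to 0 with a warning."""
    m = c.counts.astype(float)
    total = m.sum()
    po = np.trace(m) / total
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if pe >= 1.0:
        warnings.warn("chance agreement Pe = 1; kappa undefined, returning 0", stacklevel=2)
        return 0.0
    return float((po - pe) / (1.0 - pe))


def balanced_accuracy(c: ConfusionMatrix) -> float:
    """Mean per-class recall; a class with no true instances contributes 0 (warned)."""
    m = c.counts.astype(float)
    row = m.sum(axis=1)
    recalls = np.zeros(len(row))
    present = row > 0
    if not present.all():
        absent = [c.class_order[i] for i in np.flatnonzero(~present)]
        warnings.warn(f"classes with no true instances score recall 0: {absent}", stacklevel=2)
    recalls[present] = np.diag(m)[present] / row[present]
    return float(recalls.mean())


def recall_macro(c: ConfusionMatrix) -> float:
    return balanced_accuracy(c)


def specificity_macro(c: ConfusionMatrix) -> float:
    """One-vs-rest specificity TN/(TN+FP), macro-averaged over classes."""
    m = c.counts.astype(float)
    total = m.sum()
    specs = []
    for i in range(len(c.class_order)):
        fp = m[:, i].sum() - m[i, i]
        tn = total - m[i, :].sum() - m[:, i].sum() + m[i, i]
        specs.append(tn / (tn + fp) if (tn + fp) > 0 else 0.0)
    return float(np.mean(specs))


def f1_weighted(y_true, y_pred) -> float:
    return float(_sk_f1(y_true, y_pred, average="weighted", zero_division=0))


def auc_weighted(y_true, scores: np.ndarray, class_order) -> float:
    """Support-weighted one-vs-rest ROC AUC over per-class probability scores.

    Classes absent from the truth (or covering it entirely, so no negatives
    exist) are skipped with a warning and the support weights renormalized.
    """
    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=float)
    aucs, weights, skipped = [], [], []
    for i, cls in enumerate(class_order):
        pos = y_true == cls
        if pos.sum() == 0 or pos.all():
            skipped.append(cls)
            continue
        aucs.append(_sk_auc(pos.astype(int), scores[:, i]))
        weights.append(pos.sum())
    if skipped:
        warnings.warn(f"AUC skipping degenerate classes: {skipped}", stacklevel=2)
    if not aucs:
        raise DataError("AUC undefined: no class with both positives and negatives")
    return float(np.average(aucs, weights=weights))


@dataclass
class MetricSet:
    kappa: float
    balanced_accuracy: float
    f1_weighted: float
    auc_weighted: float
    recall_macro: float
    specificity_macro: float

    @classmethod
    def from_predictions(cls, y_true, y_pred, proba, class_order) -> "MetricSet":
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, class_order)
        return cls(
            kappa=kappa(cm),
            balanced_accuracy=balanced_accuracy(cm),
            f1_weighted=f1_weighted(y_true, y_pred),
            auc_weighted=auc_weighted(y_true, proba, class_order),
            recall_macro=recall_macro(cm),
            specificity_macro=specificity_macro(cm),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "kappa": self.kappa,
            "balanced_accuracy": self.balanced_accuracy,
            "f1_weighted": self.f1_weighted,
            "auc_weighted": self.auc_weighted,
            "recall_macro": self.recall_macro,
            "specificity_macro": self.specificity_macro,
        }


def evalue(kappas, bas, eps: float = EVALUE_EPS) -> float:
    """Evalue = -100 * mean(k) * mean(ba) * ln(max(sd_k * sd_ba, eps)), sample SDs."""
    kappas = np.asarray(kappas, dtype=float)
    bas = np.asarray(bas, dtype=float)
    if kappas.size < 2 or bas.size < 2:
        raise DataError("evalue needs at least 2 repeats")
    spread = max(kappas.std(ddof=1) * bas.std(ddof=1), eps)
    return float(-100.0 * kappas.mean() * bas.mean() * np.log(spread))


@dataclass
class RepeatedEvaluation:
    """Per-repeat metrics with their means, sample SDs, and the Evalue."""

    repeats: list[MetricSet]
    means: dict[str, float]
    sds: dict[str, float]
    evalue: float

    @classmethod
    def aggregate(cls, repeats: list[MetricSet]) -> "RepeatedEvaluation":
        if len(repeats) < 2:
            raise DataError("aggregation needs at least 2 repeats")
        keys = repeats[0].as_dict().keys()
        cols = {k: np.array([r.as_dict()[k] for r in repeats]) for k in keys}
        means = {k: float(v.mean()) for k, v in cols.items()}
        sds = {k: float(v.std(ddof=1)) for k, v in cols.items()}
        ev = evalue(cols["kappa"], cols["balanced_accuracy"])
        return cls(list(repeats), means, sds, ev)
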