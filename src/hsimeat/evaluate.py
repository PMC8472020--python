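"""Confusion-matrix statistics and ROC/AUC for the classification models.

Per set (calibration, cross-validation, prediction) the report carries:

* CCR — correct classification rate, 100 x trace / total (percent);
* per-class one-vs-rest TP/TN/FP/FN and the derived sensitivity
  SEN = TP/(TP+FN), specificity SPE = TN/(TN+FP) and efficiency
  EFF = sqrt(SEN x SPE), the geometric mean of the two;
* Cohen's kappa (Po - Pe)/(1 - Pe) with the standard multi-class expected
  agreement Pe = sum_i row_i x col_i / total^2;
* one-vs-rest AUC per class (Mann-Whitney ranking probability, ties half)
  and its unweighted macro mean.

Undefined metrics (empty stratum, absent class, Pe = 1) return NaN with an
:class:`UndefinedMetricWarning` rather than raising, so a report can always
be assembled. CCRs are printed to one decimal, ratio metrics to two.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import DimensionError, UndefinedMetricWarning


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (M, M); rows = true class, columns = predicted
    classes: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.classes = list(self.classes)
        m = len(self.classes)
        if self.counts.shape != (m, m):
            raise DimensionError("confusion matrix must be M x M for M classes")
        if (self.counts < 0).any():
            raise DimensionError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes) -> "ConfusionMatrix":
        classes = list(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[index[t], index[p]] += 1
        return cls(counts, classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def ccr(confusion: ConfusionMatrix) -> float:
    """Correct classification rate in percent (Eq: 100 x N1/N2)."""
    if confusion.total == 0:
        raise DimensionError("CCR undefined for an empty confusion matrix")
    return 100.0 * np.trace(confusion.counts) / confusion.total


def one_vs_rest_counts(confusion: ConfusionMatrix, cls) -> tuple:
    """(TP, TN, FP, FN) for one class against all others."""
    if cls not in confusion.classes:
        raise KeyError(f"class {cls!r} not in codebook {confusion.classes}")
    i = confusion.classes.index(cls)
    c = confusion.counts
    tp = int(c[i, i])
    fn = int(c[i].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return tp, tn, fp, fn


def sen_spe_eff(tp: int, tn: int, fp: int, fn: int) -> tuple:
    """Sensitivity, specificity and their geometric mean (efficiency)."""
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("empty positive or negative stratum; metrics undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return (np.nan, np.nan, np.nan)
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    return sen, spe, float(np.sqrt(sen * spe))


def kappa(confusion: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement over the M classes."""
    total = confusion.total
    if total == 0:
        raise DimensionError("kappa undefined for an empty confusion matrix")
    po = np.trace(confusion.counts) / total
    rows = confusion.counts.sum(axis=1)
    cols = confusion.counts.sum(axis=0)
    pe = float(rows @ cols) / total**2
    if pe == 1.0:
        warnings.warn("degenerate single-cell matrix; kappa undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return np.nan
    return (po - pe) / (1.0 - pe)


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """One-vs-rest AUC; equals the Mann-Whitney probability of correct
    ranking with ties counted one half."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        warnings.warn("one class absent; AUC undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return np.nan
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Report assembly


@dataclass
class SetMetrics:
    ccr: float
    confusion: ConfusionMatrix
    kappa: float
    per_class: dict  # class -> {tp, tn, fp, fn, sen, spe, eff, auc}
    auc_macro: float

    def to_dict(self) -> dict:
        return {
            "ccr": round(self.ccr, 1),
            "kappa": None if np.isnan(self.kappa) else round(self.kappa, 2),
            "auc_macro": None if np.isnan(self.auc_macro) else round(self.auc_macro, 2),
            "confusion": self.confusion.counts.tolist(),
            "classes": self.confusion.classes,
            "per_class": {
                c: {k: (round(v, 2) if isinstance(v, float) else v)
                    for k, v in d.items()}
                for c, d in self.per_class.items()
            },
        }


@dataclass
class EvalReport:
    """Metrics per evaluation set ('calibration', 'cross_validation', 'prediction')."""

    sets: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {name: m.to_dict() for name, m in self.sets.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = []
        for name, m in self.sets.items():
            lines.append(f"{name}: CCR = {m.ccr:.1f}%  kappa = {m.kappa:.2f}  "
                         f"macro AUC = {m.auc_macro:.2f}")
            for cls, d in m.per_class.items():
                lines.append(
                    f"  {cls}: SEN = {d['sen']:.2f}  SPE = {d['spe']:.2f}  "
                    f"EFF = {d['eff']:.2f}  AUC = {d['auc']:.2f}"
                )
        return "\n".join(lines)


def set_metrics(y_true, y_pred, classes, scores=None) -> SetMetrics:
    """All statistics for one evaluated set.

    ``scores`` is an optional (n, M) matrix of continuous per-class scores
    (column order = ``classes``) used for the ROC/AUC.
    """
    cm = ConfusionMatrix.from_labels(y_true, y_pred, classes)
    per_class = {}
    aucs = []
    for j, cls in enumerate(classes):
        tp, tn, fp, fn = one_vs_rest_counts(cm, cls)
        sen, spe, eff = sen_spe_eff(tp, tn, fp, fn)
        if scores is not None:
            auc = roc_auc(np.asarray(scores)[:, j], np.asarray(y_true) == cls)
        else:
            auc = np.nan
        per_class[cls] = dict(tp=tp, tn=tn, fp=fp, fn=fn,
                              sen=sen, spe=spe, eff=eff, auc=auc)
        aucs.append(auc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        auc_macro = float(np.nanmean(aucs)) if aucs else np.nan
    return SetMetrics(ccr=ccr(cm), confusion=cm, kappa=kappa(cm),
                      per_class=per_class, auc_macro=auc_macro)
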