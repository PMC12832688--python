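"""Evaluation statistics with pneumonia as the positive class.

Conventions: a score >= threshold predicts pneumonia; TP = pneumonia
called pneumonia, FN = pneumonia called normal, FP = normal called
pneumonia, TN = normal called normal.  Report rounding is half-up to two
decimals, matching the usual presentation of classification tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import chi2 as _chi2
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "ClassReport",
    "ROCResult",
    "McNemarResult",
    "confusion",
    "report",
    "roc_auc",
    "mcnemar",
    "discordants",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def support_pneumonia(self) -> int:
        return self.tp + self.fn

    @property
    def support_normal(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class ClassScores:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class ClassReport:
    pneumonia: ClassScores
    normal: ClassScores
    accuracy: float
    macro: tuple[float, float, float]  # (precision, recall, f1)
    weighted: tuple[float, float, float]
    zero_division: bool = False  # any score had a zero denominator

    def rounded(self, decimals: int = 2) -> dict:
        r = lambda v: round_half_up(v, decimals)
        return {
            "pneumonia": {"precision": r(self.pneumonia.precision),
                          "recall": r(self.pneumonia.recall),
                          "f1": r(self.pneumonia.f1),
                          "support": self.pneumonia.support},
            "normal": {"precision": r(self.normal.precision),
                       "recall": r(self.normal.recall),
                       "f1": r(self.normal.f1),
                       "support": self.normal.support},
            "accuracy": r(self.accuracy),
            "macro": tuple(r(v) for v in self.macro),
            "weighted": tuple(r(v) for v in self.weighted),
        }


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    chi2: float
    p: float
    corrected: bool

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def confusion(y_true, scores, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally the confusion matrix at a score threshold (pneumonia = 1)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {s.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    pred = s >= threshold
    pos = y >= 0.5
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fn=int(np.sum(~pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def report(cm: ConfusionMatrix) -> ClassReport:
    """Per-class precision/recall/F1 with macro and support-weighted
    aggregates; zero-denominator scores are 0 and flagged."""
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    flags = []

    def div(n, d):
        v, flag = _safe_div(n, d)
        flags.append(flag)
        return v

    prec_p = div(cm.tp, cm.tp + cm.fp)
    rec_p = div(cm.tp, cm.tp + cm.fn)
    f1_p = div(2 * prec_p * rec_p, prec_p + rec_p)
    prec_n = div(cm.tn, cm.tn + cm.fn)
    rec_n = div(cm.tn, cm.tn + cm.fp)
    f1_n = div(2 * prec_n * rec_n, prec_n + rec_n)
    acc = (cm.tp + cm.tn) / cm.total
    sp, sn = cm.support_pneumonia, cm.support_normal
    weighted = tuple((sp * a + sn * b) / cm.total for a, b in
                     ((prec_p, prec_n), (rec_p, rec_n), (f1_p, f1_n)))
    macro = ((prec_p + prec_n) / 2, (rec_p + rec_n) / 2, (f1_p + f1_n) / 2)
    return ClassReport(
        pneumonia=ClassScores(prec_p, rec_p, f1_p, sp),
        normal=ClassScores(prec_n, rec_n, f1_n, sn),
        accuracy=acc, macro=macro, weighted=weighted,
        zero_division=any(flags),
    )


def roc_auc(y_true, scores) -> ROCResult:
    """ROC curve over all distinct thresholds (ties grouped) and its
    trapezoidal area."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y >= 0.5)) < 2:
        raise ValueError("AUC is undefined with a single class present")
    fpr, tpr, thresholds = _sk_roc_curve((y >= 0.5).astype(int), s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def mcnemar(b: int, c: int, corrected: bool = True) -> McNemarResult:
    """McNemar's paired test on discordant counts b and c.

    chi2 = (b-c)^2/(b+c), or ((|b-c|-1)^2)/(b+c) with continuity
    correction (numerator floored at zero); p from chi-square with 1 df.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ValueError("McNemar's test is undefined with no discordant pairs")
    num = (max(abs(b - c) - 1, 0) ** 2) if corrected else (b - c) ** 2
    stat = num / (b + c)
    return McNemarResult(b=b, c=c, chi2=float(stat),
                         p=float(_chi2.sf(stat, df=1)), corrected=corrected)


def discordants(y_true, pred_a, pred_b) -> tuple[int, int]:
    """Discordant-pair counts feeding McNemar: b = A correct & B wrong,
    c = A wrong & B correct."""
    y = np.asarray(y_true)
    a = np.asarray(pred_a)
    p_b = np.asarray(pred_b)
    if not (y.shape == a.shape == p_b.shape):
        raise ValueError("length mismatch between truth and predictions")
    a_ok = a == y
    b_ok = p_b == y
    return int(np.sum(a_ok & ~b_ok)), int(np.sum(~a_ok & b_ok))
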