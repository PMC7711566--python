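"""Prognostic performance metrics on binary transition outcomes.

Confusion-matrix based indices (sensitivity, specificity, balanced
accuracy, predictive values, prognostic summary index, positive
likelihood ratio), rank-based AUC, and the Pearson chi-square test on
2x2 contingency tables used for group contrasts.

All rate metrics are kept on the percentage scale and computed on
unrounded ratios; rounding to one decimal happens only at the
presentation layer (``PrognosticMetrics.rounded``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "PrognosticMetrics",
    "confusion_counts",
    "prognostic_metrics",
    "auc",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Raw 2x2 confusion counts plus the number of unscored subjects.

    ``n_missing`` counts subjects excluded because their prediction was
    unavailable (e.g. a modality was entirely missing for them); it is
    carried along so that effective denominators are always reportable.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "n_missing"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        """Number of scored subjects."""
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PrognosticMetrics:
    """Derived prognostic indices, all rates in percent.

    Undefined ratios (zero denominators) are ``nan``; a positive
    likelihood ratio with perfect specificity is ``inf`` rather than an
    error.
    """

    sensitivity: float
    specificity: float
    bac: float
    ppv: float
    npv: float
    psi: float
    positive_lr: float
    fn_rate: float
    n: int
    n_missing: int = 0

    def rounded(self, decimals: int = 1) -> "PrognosticMetrics":
        """Presentation-layer rounding (half away from zero, as printed tables round)."""

        def r(x: float) -> float:
            if not math.isfinite(x):
                return x
            q = 10.0**decimals
            return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)

        return PrognosticMetrics(
            sensitivity=r(self.sensitivity),
            specificity=r(self.specificity),
            bac=r(self.bac),
            ppv=r(self.ppv),
            npv=r(self.npv),
            psi=r(self.psi),
            positive_lr=r(self.positive_lr),
            fn_rate=r(self.fn_rate),
            n=self.n,
            n_missing=self.n_missing,
        )


def confusion_counts(predicted, labels) -> ConfusionCounts:
    """Tally a confusion matrix from binary predictions and outcomes.

    Entries with a missing prediction (``nan``) are excluded from the
    tally and reported in ``n_missing``.
    """
    pred = np.asarray(predicted, dtype=float)
    y = np.asarray(labels, dtype=float)
    if pred.shape != y.shape or pred.ndim != 1:
        raise ValueError(
            f"predicted and labels must be equal-length 1-d vectors, got {pred.shape} vs {y.shape}"
        )
    if np.isnan(y).any():
        raise ValueError("labels must not contain missing values")
    keep = ~np.isnan(pred)
    n_missing = int((~keep).sum())
    pred, y = pred[keep], y[keep]
    for arr, name in ((pred, "predicted"), (y, "labels")):
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, n_missing=n_missing)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def prognostic_metrics(c: ConfusionCounts) -> PrognosticMetrics:
    """Derive all prognostic indices from confusion counts.

    sensitivity = 100*tp/(tp+fn), specificity = 100*tn/(tn+fp),
    BAC = (sensitivity+specificity)/2, PPV = 100*tp/(tp+fp),
    NPV = 100*tn/(tn+fn), PSI = PPV+NPV-100,
    LR+ = sensitivity/(100-specificity), FN rate = 100*fn/(tp+fn).
    """
    sens = 100.0 * _ratio(c.tp, c.tp + c.fn)
    spec = 100.0 * _ratio(c.tn, c.tn + c.fp)
    bac = (sens + spec) / 2.0
    ppv = 100.0 * _ratio(c.tp, c.tp + c.fp)
    npv = 100.0 * _ratio(c.tn, c.tn + c.fn)
    psi = ppv + npv - 100.0
    if math.isnan(spec):
        plr = float("nan")
    elif spec >= 100.0:
        plr = float("inf") if sens > 0 else float("nan")
    else:
        plr = sens / (100.0 - spec)
    fnr = 100.0 * _ratio(c.fn, c.tp + c.fn)
    return PrognosticMetrics(
        sensitivity=sens,
        specificity=spec,
        bac=bac,
        ppv=ppv,
        npv=npv,
        psi=psi,
        positive_lr=plr,
        fn_rate=fnr,
        n=c.n,
        n_missing=c.n_missing,
    )


def bac_score(labels, predicted) -> float:
    """Balanced accuracy in percent; convenience wrapper used by the CV machinery.

    If one class is absent the mean of the defined rates is returned
    (i.e. plain specificity when no positives were observed), so that
    per-fold performance stays defined on sites without transitions.
    """
    c = confusion_counts(predicted, labels)
    m = prognostic_metrics(c)
    rates = [r for r in (m.sensitivity, m.specificity) if not math.isnan(r)]
    if not rates:
        raise ValueError("no scored subjects")
    return float(np.mean(rates))


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney U normalised by n+*n-, ties 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d vectors")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(y, s))


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, without continuity correction.

    Returns ``(statistic, df, p)`` with df = 1. The uncorrected form is
    the one that matches standard printed group contrasts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("table cells must be finite and non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)
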