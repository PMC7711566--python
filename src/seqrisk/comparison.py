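"""Statistical comparison of prognostic models across CV test partitions.

Quade's rank test (an extension of the Wilcoxon signed-rank test to
k matched samples, with blocks weighted by the rank of their range)
serves as the omnibus test on a folds x models balanced-accuracy
matrix; post hoc pairwise contrasts follow the Heckert-Filliben t
approximation on Quade's weighted rank sums, with Benjamini-Hochberg
FDR over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .stability import fdr_adjust

__all__ = ["PerformanceMatrix", "quade_test", "posthoc_pairwise"]


@dataclass(frozen=True)
class PerformanceMatrix:
    """Folds x models matrix of balanced accuracies."""

    values: np.ndarray
    model_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need >= 2 folds and >= 2 models")
        if v.shape[1] != len(self.model_labels):
            raise ValueError("model_labels must match the number of columns")
        if np.isnan(v).any():
            raise ValueError("missing cells are not allowed")
        object.__setattr__(self, "values", v)


def _quade_core(values: np.ndarray):
    """Quade's weighted within-block rank statistics.

    Within-block ranks r_ij (ties averaged); block weights Q_i = rank
    of the block's range; S_ij = Q_i * (r_ij - (k+1)/2);
    A = sum S_ij^2, B = (1/b) * sum_j S_j^2.
    """
    b, k = values.shape
    r = np.apply_along_axis(rankdata, 1, values)
    ranges = values.max(axis=1) - values.min(axis=1)
    Q = rankdata(ranges)
    S = Q[:, None] * (r - (k + 1) / 2.0)
    Sj = S.sum(axis=0)
    A = float((S**2).sum())
    B = float((Sj**2).sum() / b)
    return S, Sj, A, B


def quade_test(perf: PerformanceMatrix) -> tuple[float, tuple[int, int], float]:
    """Quade omnibus test; returns (F, (df1, df2), p).

    F = (b-1) * B / (A - B) with df (k-1, (b-1)(k-1)). When every
    block is internally constant (A = 0) the statistic is undefined
    and the test is flagged non-significant (F = 0, p = 1).
    """
    v = perf.values
    b, k = v.shape
    _, _, A, B = _quade_core(v)
    df = (k - 1, (b - 1) * (k - 1))
    if A <= 0:
        return 0.0, df, 1.0
    if A == B:
        # perfect ordering agreement across all blocks: p = (1/k!)^(b-1)
        import math

        return float("inf"), df, float(math.factorial(k) ** (1 - b))
    F = (b - 1) * B / (A - B)
    p = float(stats.f.sf(F, *df))
    return float(F), df, p


def posthoc_pairwise(
    perf: PerformanceMatrix, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise model contrasts on Quade's weighted rank sums.

    |S_i - S_j| / sqrt(2 b (A - B) / ((b-1)(k-1))) is referred to the
    t distribution with (b-1)(k-1) df (Heckert-Filliben form); two-
    sided p values are BH-FDR adjusted over all k(k-1)/2 pairs.
    Returns ``(adjusted p matrix, mean-difference matrix)``, both
    symmetric; the p diagonal is 1, the difference diagonal 0.
    """
    v = perf.values
    b, k = v.shape
    _, Sj, A, B = _quade_core(v)
    df = (b - 1) * (k - 1)
    denom_sq = 2.0 * b * (A - B) / df
    p = np.ones((k, k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = []
    for i, j in pairs:
        if denom_sq <= 0:
            raw.append(1.0 if Sj[i] == Sj[j] else 0.0)
            continue
        t = abs(Sj[i] - Sj[j]) / np.sqrt(denom_sq)
        raw.append(float(2.0 * stats.t.sf(t, df)))
    if pairs:
        adj, _ = fdr_adjust(np.asarray(raw), alpha=alpha)
        for (i, j), pa in zip(pairs, adj):
            p[i, j] = p[j, i] = pa
    mean_diff = v.mean(axis=0)[:, None] - v.mean(axis=0)[None, :]
    return p, mean_diff
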