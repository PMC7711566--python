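"""Sequential deferral workflows with percentile propagation cutoffs.

A workflow orders prognostic stages (a single model or a cumulative
multimodal stack per stage) and passes only prognostically ambiguous
cases forward: at each stage, subjects whose decision-score
percentile falls below the lower cutoff exit as confident negatives,
those above the upper cutoff exit as confident positives, and those
inside the window are deferred to the next assessment. At the final
stage, still-deferred cases are decided by score sign. Workflow
search maximizes a convex blend of balanced accuracy and assessment
parsimony controlled by the regularization strength gamma in [0, 1]:

    J = (1 - gamma) * BAC/100 + gamma * (1 - mean_assessments / max_assessments)

so gamma = 0 optimizes accuracy alone and gamma = 1 collapses to a
single assessment for everyone.

Percentiles are computed transductively on the score distribution of
the subjects actually entering a stage. Tied scores straddling a
cutoff are all deferred (a tie group exits only when it lies entirely
outside the window).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .metrics import PrognosticMetrics, confusion_counts, prognostic_metrics

__all__ = [
    "WorkflowSpec",
    "StageRecord",
    "WorkflowTrace",
    "propagate",
    "evaluate_workflow",
    "optimize_workflow",
]


@dataclass(frozen=True)
class WorkflowSpec:
    """An ordered stage list with shared propagation cutoffs and gamma."""

    sequence: tuple[str, ...]
    lower_pct: float
    upper_pct: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.sequence)) != len(self.sequence) or not self.sequence:
            raise ValueError("sequence must be a non-empty list of distinct stage ids")
        if not (0 <= self.lower_pct <= self.upper_pct <= 100):
            raise ValueError("cutoffs must satisfy 0 <= lower <= upper <= 100")
        if not (0 <= self.gamma <= 1):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class StageRecord:
    stage: str
    n_in: int
    decided_negative: np.ndarray
    decided_positive: np.ndarray
    deferred: np.ndarray


@dataclass
class WorkflowTrace:
    """Per-stage decision trail and final assessment-burden summary."""

    spec: WorkflowSpec
    stages: list[StageRecord]
    final_labels: np.ndarray
    metrics: PrognosticMetrics
    fraction_full_battery: float
    mean_assessments: float


def _tie_group_percentiles(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hazen percentile range of each subject's tie group.

    For distinct scores both bounds equal 100*(rank - 0.5)/n; tied
    subjects share the ordinal rank span of their group.
    """
    n = len(scores)
    r_min = rankdata(scores, method="min")
    r_max = rankdata(scores, method="max")
    return 100.0 * (r_min - 0.5) / n, 100.0 * (r_max - 0.5) / n


def propagate(scores, lower_pct: float, upper_pct: float):
    """Partition subjects into decided-negative / decided-positive / deferred.

    A subject exits negative when its whole tie group sits below the
    lower percentile cutoff, positive when it sits entirely above the
    upper cutoff; everything inside (or straddling) the window
    [lower, upper] is deferred. Returns index arrays
    ``(negative, positive, deferred)`` into ``scores``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    if not (0 <= lower_pct <= upper_pct <= 100):
        raise ValueError("cutoffs must satisfy 0 <= lower <= upper <= 100")
    if np.isnan(s).any():
        raise ValueError("scores contain missing values")
    pct_lo, pct_hi = _tie_group_percentiles(s)
    neg = pct_hi < lower_pct
    pos = pct_lo > upper_pct
    defer = ~(neg | pos)
    return np.flatnonzero(neg), np.flatnonzero(pos), np.flatnonzero(defer)


def evaluate_workflow(
    spec: WorkflowSpec,
    stage_scores: dict[str, np.ndarray],
    labels,
    on_missing: str = "error",
) -> WorkflowTrace:
    """Run a workflow over precomputed out-of-fold stage scores.

    ``stage_scores`` maps each stage id to a full-cohort score vector;
    a stage only ever consults the entries of subjects deferred into
    it, and its percentile cutoffs are taken over exactly those
    subjects. Subjects deferred into a stage with a missing score
    raise (``on_missing='error'``) or are force-deferred onward with a
    warning (``on_missing='defer'``).
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    for stage in spec.sequence:
        if stage not in stage_scores:
            raise KeyError(f"no scores for stage {stage!r}")
    final = np.full(n, -1, dtype=int)
    assessments = np.zeros(n, dtype=int)
    current = np.arange(n)
    records: list[StageRecord] = []
    entered_last = 0
    for t, stage in enumerate(spec.sequence):
        is_last = t == len(spec.sequence) - 1
        if current.size == 0:
            records.append(
                StageRecord(stage, 0, np.empty(0, int), np.empty(0, int), np.empty(0, int))
            )
            continue
        if is_last:
            entered_last = current.size
        s = np.asarray(stage_scores[stage], dtype=float)[current]
        if np.isnan(s).any():
            if on_missing == "error":
                raise ValueError(
                    f"stage {stage!r}: missing scores for deferred subjects"
                )
            import warnings

            warnings.warn(f"stage {stage!r}: deferring subjects with missing scores")
            missing_local = np.isnan(s)
            s = np.where(missing_local, 0.0, s)
        else:
            missing_local = np.zeros(current.size, dtype=bool)
        assessments[current] += 1
        neg_l, pos_l, def_l = propagate(s, spec.lower_pct, spec.upper_pct)
        if missing_local.any():
            keep = lambda idx: idx[~missing_local[idx]]  # noqa: E731
            forced = np.flatnonzero(missing_local)
            neg_l, pos_l = keep(neg_l), keep(pos_l)
            def_l = np.union1d(def_l, forced)
        neg, pos, deferred = current[neg_l], current[pos_l], current[def_l]
        if is_last:
            sign_pos = deferred[s[def_l] > 0]
            sign_neg = deferred[s[def_l] <= 0]
            pos = np.concatenate([pos, sign_pos])
            neg = np.concatenate([neg, sign_neg])
            deferred = np.empty(0, dtype=int)
        final[neg] = 0
        final[pos] = 1
        records.append(StageRecord(stage, len(current), neg, pos, deferred))
        current = deferred
    assert (final >= 0).all(), "every subject must receive exactly one final label"
    m = prognostic_metrics(confusion_counts(final.astype(float), y))
    frac_full = entered_last / n if len(spec.sequence) > 1 else 0.0
    return WorkflowTrace(
        spec=spec,
        stages=records,
        final_labels=final,
        metrics=m,
        fraction_full_battery=float(frac_full),
        mean_assessments=float(assessments.mean()),
    )


def _objective(trace: WorkflowTrace, gamma: float, max_assessments: int) -> float:
    bac = trace.metrics.bac
    parsimony = 1.0 - trace.mean_assessments / max_assessments
    return (1.0 - gamma) * bac / 100.0 + gamma * parsimony


def optimize_workflow(
    candidate_stages,
    stage_scores: dict[str, np.ndarray],
    labels,
    gamma: float,
    cutoff_grid,
    sequences=None,
) -> tuple[WorkflowSpec, WorkflowTrace]:
    """Exhaustive search over stage orderings and shared cutoff pairs.

    Maximizes J = (1-gamma)*BAC/100 + gamma*(1 - mean_assessments /
    max_assessments) over all permutations of ``candidate_stages``
    (or the explicit ``sequences`` iterable) and all cutoff pairs
    (lower, upper) with lower <= upper drawn from ``cutoff_grid``.
    Ties are broken toward fewer assessments, then higher balanced
    accuracy (so a fully parsimony-driven search at gamma = 1 still
    returns the most accurate single-assessment rule), then
    lexicographically by (sequence, cutoffs).
    """
    candidate_stages = list(candidate_stages)
    if not candidate_stages:
        raise ValueError("at least one candidate stage is required")
    grid = sorted(float(g) for g in cutoff_grid)
    if not grid:
        raise ValueError("cutoff_grid must be non-empty")
    if sequences is None:
        sequences = itertools.permutations(candidate_stages)
    sequences = [tuple(s) for s in sequences]
    max_assessments = max(len(s) for s in sequences)
    pairs = [(lo, hi) for lo in grid for hi in grid if lo <= hi]
    best = None
    for seq in sequences:
        for lo, hi in pairs:
            spec = WorkflowSpec(sequence=seq, lower_pct=lo, upper_pct=hi, gamma=gamma)
            trace = evaluate_workflow(spec, stage_scores, labels)
            key = (
                -round(_objective(trace, gamma, max_assessments), 12),
                trace.mean_assessments,
                -trace.metrics.bac,
                seq,
                (lo, hi),
            )
            if best is None or key < best[0]:
                best = (key, spec, trace)
    return best[1], best[2]
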