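"""Stacked generalization over unimodal out-of-fold decision scores.

The meta-learner is the same linear max-margin family as the base
learners and is trained under the SAME outer fold plan, on base
scores that are strictly out-of-fold: a subject's base score always
comes from models trained without that subject, and the meta-model
scoring a held-out site never saw that site. Appending the binary
clinician estimate as an extra predictor yields the "cybernetic"
variant that fuses algorithmic and human prognoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .validation import FoldPlan, NestedLinearRiskCalculator, OOFScores

__all__ = ["StackSpec", "stack", "StackedRiskCalculator"]


@dataclass(frozen=True)
class StackSpec:
    """Which base models feed the stack, and whether the rater joins them."""

    inputs: tuple[str, ...]
    include_rater: bool = False
    learner_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.inputs) < 1:
            raise ValueError("a stack needs at least one input model")


class StackedRiskCalculator(NestedLinearRiskCalculator):
    """Meta-learner over out-of-fold base scores.

    Identical nested-CV machinery as the unimodal calculators; its
    design matrix is the (subjects x base models) OOF score matrix,
    optionally with the rater column appended last. The outer FoldPlan
    must be the one the base scores were produced under, otherwise the
    meta level would train on scores from models that saw its test
    subjects (a leakage error).
    """

    def fit_stack(
        self,
        oof: dict[str, OOFScores],
        labels,
        plan: FoldPlan,
        spec: StackSpec,
        rater=None,
    ):
        missing = [m for m in spec.inputs if m not in oof]
        if missing:
            raise KeyError(f"no OOF scores for stack inputs {missing}")
        cols = [np.asarray(oof[m].scores, dtype=float) for m in spec.inputs]
        names = list(spec.inputs)
        if spec.include_rater:
            if rater is None:
                raise ValueError("StackSpec.include_rater is set but no rater vector given")
            cols.append(np.asarray(rater, dtype=float))
            names.append("rater")
        S = np.column_stack(cols)
        y = np.asarray(labels, dtype=int)
        n = len(y)
        if S.shape[0] != n:
            raise ValueError("OOF score matrix and labels disagree in length")
        for m in spec.inputs:
            if oof[m].n != n:
                raise ValueError(
                    f"OOF scores of {m!r} cover {oof[m].n} subjects, expected {n}: "
                    "base and meta level must share one FoldPlan"
                )
            for site, (_, test) in plan.outer_folds.items():
                if not (np.asarray(oof[m].sites)[test] == site).all():
                    raise ValueError(
                        f"leakage: OOF scores of {m!r} were not produced under "
                        "the meta-level FoldPlan"
                    )
        complete = ~np.isnan(S).any(axis=1)
        self.n_excluded_ = int((~complete).sum())
        self.feature_names_ = names
        if self.n_excluded_ == 0:
            super().fit(S, y, plan=plan)
            self.stack_oof_ = self.oof_
            return self
        # complete-case stacking: rebuild folds on the retained subjects,
        # keeping the shared plan's inner-fold geometry and seed
        from .validation import make_losocv_folds

        sites = np.empty(n, dtype=object)
        for site, (_, test) in plan.outer_folds.items():
            sites[test] = site
        sub_plan = make_losocv_folds(
            sites[complete], y[complete],
            n_inner_folds=plan.n_inner_folds, repeats=plan.repeats, seed=plan.seed,
        )
        super().fit(S[complete], y[complete], plan=sub_plan)
        scores = np.full(n, np.nan)
        pred = np.full(n, np.nan)
        scores[complete] = self.oof_.scores
        pred[complete] = self.oof_.predicted
        self.stack_oof_ = OOFScores(scores=scores, predicted=pred, sites=sites)
        return self


def stack(
    oof: dict[str, OOFScores],
    labels,
    plan: FoldPlan,
    spec: StackSpec,
    rater=None,
):
    """Train the stacked (or cybernetic, with rater) meta-model.

    Returns ``(StackedRiskCalculator, OOFScores)`` with meta-level
    out-of-fold scores. Subjects missing any input score are excluded
    and counted in ``estimator.n_excluded_``.
    """
    est = StackedRiskCalculator(**spec.learner_config)
    est.fit_stack(oof, labels, plan, spec, rater=rater)
    return est, est.stack_oof_
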