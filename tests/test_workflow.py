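"""Sequential deferral: propagation cutoffs, traces, gamma optimization."""

import numpy as np
import pytest

from seqrisk import (
    WorkflowSpec,
    confusion_counts,
    evaluate_workflow,
    optimize_workflow,
    propagate,
)
from seqrisk.workflow import _tie_group_percentiles


class TestPropagate:
    def test_empty_window_defers_nobody(self, rng):
        s = rng.normal(size=50)
        neg, pos, deferred = propagate(s, 0.0, 0.0)
        assert deferred.size == 0
        assert neg.size + pos.size == 50

    def test_quarter_cutoff_forces_exact_counts(self):
        s = np.random.default_rng(0).permutation(200).astype(float)  # distinct
        neg, pos, deferred = propagate(s, 25.0, 100.0)
        assert (len(neg), len(pos), len(deferred)) == (50, 0, 150)
        # the decided negatives are exactly the lowest quarter
        assert set(neg) == set(np.argsort(s)[:50])

    def test_ties_straddling_cutoff_are_all_deferred(self):
        """A tie group spanning the cutoff defers as a unit; counts match
        brute-force enumeration over the tie group's rank span."""
        s = np.array([0.0] * 10 + [1.0] * 20 + [2.0] * 70)  # ties at the cutoff
        lower = 25.0  # 25th percentile falls inside the 1.0-group (ranks 11-30)
        neg, pos, deferred = propagate(s, lower, 100.0)
        lo, hi = _tie_group_percentiles(s)
        expect_neg = np.flatnonzero(hi < lower)
        assert set(neg) == set(expect_neg)
        assert set(deferred) >= set(np.flatnonzero(s == 1.0))

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            propagate([1.0, 2.0], 60.0, 40.0)
        with pytest.raises(ValueError):
            propagate([], 0.0, 100.0)


def _toy_scores(rng, n=200, informative=0.9):
    """Labels plus a score vector whose sign encodes the label with
    probability `informative`."""
    y = (rng.random(n) < 0.2).astype(int)
    flip = rng.random(n) > informative
    s = np.where(y ^ flip, 1.0, -1.0) * rng.uniform(0.5, 2.0, n)
    return y, s


class TestEvaluateWorkflow:
    def test_single_stage_equals_plain_evaluation(self, rng):
        y, s = _toy_scores(rng)
        spec = WorkflowSpec(sequence=("a",), lower_pct=0, upper_pct=100)
        trace = evaluate_workflow(spec, {"a": s}, y)
        plain = confusion_counts((s > 0).astype(float), y)
        got = confusion_counts(trace.final_labels.astype(float), y)
        assert plain == got
        assert trace.fraction_full_battery == 0.0

    def test_defer_everyone_equals_final_model_alone(self, rng):
        y, s1 = _toy_scores(rng, informative=0.6)
        _, s2 = _toy_scores(rng, informative=0.95)
        spec = WorkflowSpec(sequence=("weak", "strong"), lower_pct=0, upper_pct=100)
        trace = evaluate_workflow(spec, {"weak": s1, "strong": s2}, y)
        np.testing.assert_array_equal(trace.final_labels, (s2 > 0).astype(int))
        assert trace.fraction_full_battery == 1.0
        assert trace.mean_assessments == 2.0

    def test_empty_window_at_stage1_sends_nobody_on(self, rng):
        y, s1 = _toy_scores(rng)
        _, s2 = _toy_scores(rng)
        spec = WorkflowSpec(sequence=("a", "b"), lower_pct=0, upper_pct=0)
        trace = evaluate_workflow(spec, {"a": s1, "b": s2}, y)
        assert trace.fraction_full_battery == 0.0
        assert trace.mean_assessments == 1.0

    def test_conservation_at_every_stage(self, rng):
        y, s1 = _toy_scores(rng)
        _, s2 = _toy_scores(rng)
        _, s3 = _toy_scores(rng)
        spec = WorkflowSpec(sequence=("a", "b", "c"), lower_pct=25, upper_pct=87.5)
        trace = evaluate_workflow(spec, {"a": s1, "b": s2, "c": s3}, y)
        for rec in trace.stages:
            assert len(rec.decided_negative) + len(rec.decided_positive) + len(rec.deferred) == rec.n_in
        # every subject labelled exactly once
        labelled = np.concatenate(
            [np.concatenate([r.decided_negative, r.decided_positive]) for r in trace.stages]
        )
        assert sorted(labelled) == list(range(len(y)))

    def test_more_accurate_second_stage_never_hurts(self):
        """If stage 2 scores are strictly better on deferred cases, the
        two-stage workflow's BAC is at least stage 1's (median over seeds)."""
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y, s1 = _toy_scores(rng, informative=0.7)
            s2 = np.where(y == 1, 1.0, -1.0)  # oracle second stage
            spec = WorkflowSpec(sequence=("a", "b"), lower_pct=12.5, upper_pct=100)
            trace = evaluate_workflow(spec, {"a": s1, "b": s2}, y)
            from seqrisk.metrics import bac_score

            deltas.append(trace.metrics.bac - bac_score(y, (s1 > 0).astype(int)))
        assert np.median(deltas) >= 0

    def test_missing_stage_scores_raise(self, rng):
        y, s1 = _toy_scores(rng)
        s2 = np.full_like(s1, np.nan)
        spec = WorkflowSpec(sequence=("a", "b"), lower_pct=0, upper_pct=100)
        with pytest.raises(ValueError, match="missing"):
            evaluate_workflow(spec, {"a": s1, "b": s2}, y)


GRID = tuple(np.arange(0.0, 100.1, 12.5))


class TestOptimizeWorkflow:
    def _stage_scores(self, seed=0):
        rng = np.random.default_rng(seed)
        y, s1 = _toy_scores(rng, informative=0.75)
        _, s2 = _toy_scores(rng, informative=0.8)
        s2 = np.where(rng.random(len(y)) < 0.8, np.where(y == 1, abs(s2), -abs(s2)), s2)
        _, s3 = _toy_scores(rng, informative=0.9)
        return y, {"a": s1, "b": s2, "c": s3}

    def test_gamma_one_gives_single_assessment(self):
        y, scores = self._stage_scores()
        spec, trace = optimize_workflow(list(scores), scores, y, 1.0, GRID)
        assert trace.mean_assessments == 1.0
        assert trace.fraction_full_battery == 0.0

    def test_gamma_zero_dominates_every_single_stage(self):
        from seqrisk.metrics import bac_score

        y, scores = self._stage_scores()
        spec, trace = optimize_workflow(list(scores), scores, y, 0.0, GRID)
        best_single = max(
            bac_score(y, (s > 0).astype(int)) for s in scores.values()
        )
        assert trace.metrics.bac >= best_single

    def test_full_battery_fraction_monotone_in_gamma(self):
        y, scores = self._stage_scores(seed=5)
        fracs = []
        for g in (0.0, 0.25, 0.5, 0.75, 1.0):
            _, trace = optimize_workflow(list(scores), scores, y, g, GRID)
            fracs.append(trace.fraction_full_battery)
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 0.0

    def test_empty_grid_rejected(self):
        y, scores = self._stage_scores()
        with pytest.raises(ValueError, match="cutoff_grid"):
            optimize_workflow(list(scores), scores, y, 0.0, [])
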