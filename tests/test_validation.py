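"""Leave-one-site-out nested CV: fold geometry, leakage, permutation test."""

import warnings

import numpy as np
import pytest

from seqrisk import (
    NestedLinearRiskCalculator,
    make_losocv_folds,
    permutation_test,
    train_unimodal,
)
from seqrisk.metrics import bac_score
from seqrisk.validation import _FittedModel, _preprocess_fit, _svm_fit, _transform

from conftest import FAST_LEARNER, small_cohort


class TestFoldPlan:
    def test_seven_sites_give_seven_disjoint_covering_folds(self, default_cohort):
        c = default_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = make_losocv_folds(c.sites, c.labels, n_inner_folds=5, seed=0)
        assert len(plan.outer_folds) == 7
        tests = [te for _, te in plan.outer_folds.values()]
        allt = np.concatenate(tests)
        assert len(allt) == c.n and len(np.unique(allt)) == c.n
        for site, (tr, te) in plan.outer_folds.items():
            assert (c.sites[te] == site).all()
            assert not np.intersect1d(tr, te).size

    def test_inner_folds_stay_inside_outer_train(self, cohort_small):
        plan = make_losocv_folds(cohort_small.sites, cohort_small.labels, 4, seed=0)
        plan.validate()  # raises on any leakage

    def test_fixed_seed_reproduces_plan(self, cohort_small):
        a = make_losocv_folds(cohort_small.sites, cohort_small.labels, 4, seed=9)
        b = make_losocv_folds(cohort_small.sites, cohort_small.labels, 4, seed=9)
        for s in a.outer_folds:
            for x, y_ in zip(a.inner_folds[s], b.inner_folds[s]):
                np.testing.assert_array_equal(x[0], y_[0])

    def test_two_singleton_sites_cannot_stratify(self):
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                make_losocv_folds(["a", "b"], [1, 0], n_inner_folds=2, seed=0)

    def test_single_class_site_warns(self):
        sites = ["a"] * 20 + ["b"] * 20 + ["c"] * 10
        y = [0, 1] * 10 + [1, 0] * 10 + [0] * 10  # site c has no transitions
        with pytest.warns(UserWarning, match="single outcome class"):
            make_losocv_folds(sites, y, n_inner_folds=2, seed=0)

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(ValueError, match="2 sites"):
            make_losocv_folds(["a"] * 10, [0, 1] * 5, n_inner_folds=2, seed=0)


class TestNestedCalculator:
    def test_oof_scores_cover_every_subject_once(self, cohort_small, plan_small):
        est, oof = train_unimodal(cohort_small, "clinical", plan=plan_small, **FAST_LEARNER)
        assert oof.n == cohort_small.n
        assert not np.isnan(oof.scores).any()
        # weights: one row per inner model per outer fold
        n_models = sum(len(v) for v in plan_small.inner_folds.values())
        assert est.weights_.shape == (n_models, 20)

    def test_strong_signal_beats_seventy_bac(self):
        """Planted clinical signal (scaled-down cohort, effect 1.5) is
        recovered well above chance: median out-of-fold BAC > 70%."""
        bacs = []
        for seed in range(5):
            c = small_cohort(seed=seed, effect_size={"clinical": 1.5, "prs": 0.5, "smri": 0.5})
            _, oof = train_unimodal(c, "clinical", **FAST_LEARNER, seed=seed)
            bacs.append(bac_score(c.labels, oof.predicted.astype(int)))
        assert np.median(bacs) > 70

    def test_null_signal_hovers_at_chance(self):
        """Without any planted effect, out-of-fold BAC stays in [40, 60]
        for at least 90% of seeds."""
        inside = 0
        n_seeds = 20
        for seed in range(n_seeds):
            c = small_cohort(
                seed=seed,
                effect_size={m: 0.0 for m in ("clinical", "prs", "smri")},
            )
            _, oof = train_unimodal(c, "clinical", **FAST_LEARNER, seed=seed)
            b = bac_score(c.labels, oof.predicted.astype(int))
            inside += 40 <= b <= 60
        assert inside >= 0.9 * n_seeds

    def test_fixed_seed_gives_identical_oof(self, cohort_small):
        a = train_unimodal(cohort_small, "clinical", **FAST_LEARNER, seed=5)[1]
        b = train_unimodal(cohort_small, "clinical", **FAST_LEARNER, seed=5)[1]
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_no_leakage_corrupting_heldout_subject(self, cohort_small, plan_small):
        """Corrupting a held-out subject's features must not change the
        fitted weights of its own outer fold's models."""
        est, _ = train_unimodal(cohort_small, "clinical", plan=plan_small, **FAST_LEARNER)
        site = est.plan_.sites[0]
        test_idx = est.plan_.outer_folds[site][1]
        X = cohort_small.blocks["clinical"].copy()
        X[test_idx[0]] = 1e6  # garbage features for one held-out subject
        est2 = NestedLinearRiskCalculator(**FAST_LEARNER)
        est2.fit(X, cohort_small.labels, plan=plan_small)
        for m1, m2 in zip(est.models_[site], est2.models_[site]):
            np.testing.assert_array_equal(m1.coef, m2.coef)
            assert m1.intercept == m2.intercept

    def test_duplicated_separable_data_leave_margin_fit_unchanged(self, rng):
        """On separable data at large C the max-margin rule is invariant
        to duplicating every subject (deterministic-fitting sanity)."""
        X = np.vstack([rng.normal(-2, 0.3, (20, 4)), rng.normal(2, 0.3, (20, 4))])
        y = np.array([0] * 20 + [1] * 20)
        grid = rng.normal(size=(10, 4))

        def fit_decide(Xf, yf):
            med, mean, scale = _preprocess_fit(Xf)
            w, b = _svm_fit(_transform(Xf, med, mean, scale), yf, C=100.0, max_iter=100000)
            return _transform(grid, med, mean, scale) @ w + b

        d1 = fit_decide(X, y)
        d2 = fit_decide(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_single_class_training_rejected(self, cohort_small):
        y = np.zeros(cohort_small.n, dtype=int)
        est = NestedLinearRiskCalculator(**FAST_LEARNER)
        with pytest.raises(ValueError, match="single outcome class"):
            est.fit(cohort_small.blocks["clinical"], y, sites=cohort_small.sites)

    def test_all_missing_column_warns(self, cohort_small, plan_small):
        X = cohort_small.blocks["clinical"].copy()
        X[:, 3] = np.nan
        est = NestedLinearRiskCalculator(**FAST_LEARNER)
        with pytest.warns(UserWarning, match="all-missing"):
            est.fit(X, cohort_small.labels, plan=plan_small)

    def test_unknown_modality_rejected(self, cohort_small):
        with pytest.raises(KeyError):
            train_unimodal(cohort_small, "eeg")


class TestPermutationTest:
    def test_identity_evaluation_reproduces_observed(self, cohort_small, plan_small):
        def evaluate(labels):
            est = NestedLinearRiskCalculator(**FAST_LEARNER, seed=1)
            est.fit(cohort_small.blocks["prs"], labels, sites=cohort_small.sites)
            return bac_score(labels, (est.oof_.scores > 0).astype(int))

        obs = evaluate(cohort_small.labels)
        res = permutation_test(evaluate, cohort_small.labels, n_permutations=3, seed=0)
        assert res.observed == obs

    def test_overwhelming_signal_hits_lower_bound(self):
        """A pipeline that trivially separates the classes gives
        p = 1/(B+1), the smallest attainable value."""
        y = np.array([0, 1] * 30)

        def evaluate(labels):
            # deterministic surrogate: BAC of a perfect memorizer of y
            return bac_score(labels, y)

        res = permutation_test(evaluate, y, n_permutations=99, seed=1)
        assert res.p == pytest.approx(1 / 100)

    def test_invalid_permutation_count(self):
        with pytest.raises(ValueError):
            permutation_test(lambda y: 50.0, [0, 1], n_permutations=0)
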