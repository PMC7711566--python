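"""Leave-one-site-out nested cross-validation around a linear max-margin learner.

The outer loop holds out one recruitment site at a time (testing
geographic transportability); the inner loop selects the margin
penalty by stratified k-fold balanced accuracy within each outer
training set. Preprocessing (median imputation, z-scaling) is learned
strictly on training splits — no statistic ever sees a held-out
subject. Held-out sites are scored by the mean decision value of the
inner-model ensemble, yielding pooled out-of-fold (OOF) scores: the
currency passed on to stacking and workflow construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

from .metrics import bac_score

__all__ = [
    "FoldPlan",
    "make_losocv_folds",
    "NestedLinearRiskCalculator",
    "OOFScores",
    "train_unimodal",
    "permutation_test",
    "PermutationResult",
]

DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-6, 7))


@dataclass(frozen=True)
class FoldPlan:
    """Nested outer (leave-one-site-out) / inner CV assignment.

    ``outer_folds`` maps each held-out site to ``(train_idx, test_idx)``
    global index arrays; ``inner_folds[site]`` lists ``(train, val)``
    splits whose indices are all drawn from that site's outer training
    set (the no-leakage guarantee).
    """

    outer_folds: dict[str, tuple[np.ndarray, np.ndarray]]
    inner_folds: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    n_inner_folds: int
    repeats: int
    seed: int

    @property
    def sites(self) -> list[str]:
        return list(self.outer_folds)

    def validate(self) -> None:
        all_test = np.concatenate([t for _, t in self.outer_folds.values()])
        if len(np.unique(all_test)) != len(all_test):
            raise ValueError("outer test sets overlap")
        for site, (tr, te) in self.outer_folds.items():
            if np.intersect1d(tr, te).size:
                raise ValueError(f"outer fold {site!r}: train/test overlap")
            train_set = set(tr.tolist())
            for itr, iva in self.inner_folds[site]:
                if not (set(itr.tolist()) <= train_set and set(iva.tolist()) <= train_set):
                    raise ValueError(f"inner folds of {site!r} leak outside outer-train")


def make_losocv_folds(
    sites,
    labels,
    n_inner_folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> FoldPlan:
    """Build the leave-one-site-out fold plan with stratified inner folds.

    One outer fold per site; inner folds are stratified by outcome
    within the outer training set. Sites that lack one of the two
    classes in the pooled data trigger a warning (their outer-train
    sets are still valid as long as both classes remain present).
    """
    sites = np.asarray(sites)
    y = np.asarray(labels, dtype=int)
    if sites.shape != y.shape:
        raise ValueError("sites and labels must have equal length")
    uniq = list(dict.fromkeys(sites.tolist()))  # order of first appearance
    if len(uniq) < 2:
        raise ValueError("leave-one-site-out requires at least 2 sites")
    for s in uniq:
        ys = y[sites == s]
        if len(np.unique(ys)) < 2:
            warnings.warn(
                f"site {s!r} contains a single outcome class; its held-out "
                "metrics will be one-sided",
                stacklevel=2,
            )
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(uniq))
    outer: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    inner: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for s, cs in zip(uniq, child_seeds):
        test = np.flatnonzero(sites == s)
        train = np.flatnonzero(sites != s)
        y_tr = y[train]
        counts = np.bincount(y_tr, minlength=2)
        if counts.min() < 1:
            raise ValueError(
                f"outer-train for held-out site {s!r} contains a single class"
            )
        if counts.min() < n_inner_folds:
            raise ValueError(
                f"cannot stratify {n_inner_folds} inner folds for held-out site "
                f"{s!r}: minority class has only {counts.min()} subjects"
            )
        if repeats > 1:
            splitter = RepeatedStratifiedKFold(
                n_splits=n_inner_folds, n_repeats=repeats, random_state=int(cs % 2**31)
            )
        else:
            splitter = StratifiedKFold(
                n_splits=n_inner_folds, shuffle=True, random_state=int(cs % 2**31)
            )
        inner[s] = [
            (train[itr], train[iva]) for itr, iva in splitter.split(train[:, None], y_tr)
        ]
        outer[s] = (train, test)
    plan = FoldPlan(
        outer_folds=outer,
        inner_folds=inner,
        n_inner_folds=n_inner_folds,
        repeats=repeats,
        seed=seed,
    )
    plan.validate()
    return plan


@dataclass
class OOFScores:
    """Pooled out-of-fold decision values.

    Every subject is scored exactly once, by the ensemble of the outer
    fold that held its site out. ``predicted`` applies the decision
    threshold 0.
    """

    scores: np.ndarray
    predicted: np.ndarray
    sites: np.ndarray

    @property
    def n(self) -> int:
        return len(self.scores)


class _FittedModel:
    """One inner model: its training-split preprocessing + linear rule."""

    __slots__ = ("median", "mean", "scale", "coef", "intercept")

    def __init__(self, median, mean, scale, coef, intercept):
        self.median = median
        self.mean = mean
        self.scale = scale
        self.coef = coef
        self.intercept = intercept

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = _transform(X, self.median, self.mean, self.scale)
        return Z @ self.coef + self.intercept


def _preprocess_fit(X: np.ndarray):
    """Median-imputation and z-scaling parameters from a training split."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        median = np.nanmedian(X, axis=0)
    bad = ~np.isfinite(median)
    if bad.any():
        median = np.where(bad, 0.0, median)
    Xi = np.where(np.isnan(X), median, X)
    mean = Xi.mean(axis=0)
    scale = Xi.std(axis=0)
    scale[scale == 0] = 1.0
    return median, mean, scale


def _transform(X, median, mean, scale):
    Xi = np.where(np.isnan(X), median, X)
    return (Xi - mean) / scale


def _svm_fit(Z, y, C, max_iter, gram=None):
    """Linear hinge-loss SVM with inverse-frequency class weights.

    Fit in the dual on a (possibly precomputed) Gram matrix — libsvm is
    deterministic and fast at this sample size — then fold the support
    vectors back into a primal weight vector in standardized space.
    """
    if gram is None:
        gram = Z @ Z.T
    clf = SVC(C=C, kernel="precomputed", class_weight="balanced", max_iter=max_iter)
    with warnings.catch_warnings():
        # very large C values may hit the iteration cap; the truncated
        # solution is still a valid (slightly under-optimized) margin fit
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(gram, y)
    w = clf.dual_coef_.ravel() @ Z[clf.support_]
    return w, float(clf.intercept_[0])


class NestedLinearRiskCalculator(BaseEstimator, ClassifierMixin):
    """Nested-CV linear max-margin risk calculator.

    An L2-regularized linear SVM with inverse-frequency class weights
    (required to reach a high-sensitivity regime at ~8% outcome
    prevalence), wrapped in leave-one-site-out nested cross-validation.

    Parameters
    ----------
    C_grid : sequence of float
        Margin-penalty grid searched by inner-fold balanced accuracy
        (default 2**-6 .. 2**6).
    n_inner_folds, repeats : int
        Inner stratified k-fold geometry.
    seed : int
        Drives fold shuffling; fits themselves are deterministic.

    Attributes (after ``fit``)
    --------------------------
    plan_ : FoldPlan
    oof_ : OOFScores -- pooled out-of-fold scores and labels.
    weights_ : ndarray, (n_models, n_features) -- inner-model weight
        vectors in standardized feature space, the input to stability
        mapping.
    best_C_ : dict site -> selected penalty.
    fold_bac_ : dict site -> held-out balanced accuracy (percent).
    """

    def __init__(
        self,
        C_grid: Sequence[float] = DEFAULT_C_GRID,
        n_inner_folds: int = 10,
        repeats: int = 1,
        seed: int = 0,
        max_iter: int = 20_000,
    ):
        self.C_grid = C_grid
        self.n_inner_folds = n_inner_folds
        self.repeats = repeats
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X, y, sites=None, plan: FoldPlan | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-d with one row per subject")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contain a single outcome class")
        if plan is None:
            if sites is None:
                raise ValueError("either sites or a FoldPlan must be provided")
            plan = make_losocv_folds(
                sites, y, self.n_inner_folds, self.repeats, self.seed
            )
        self.plan_ = plan
        dead = np.flatnonzero(np.isnan(X).all(axis=0))
        if dead.size:
            warnings.warn(
                f"{dead.size} all-missing feature column(s) {dead.tolist()[:5]}... "
                "carry no information and are effectively dropped (imputed constant)",
                stacklevel=2,
            )

        n = len(y)
        oof = np.full(n, np.nan)
        self.models_: dict[str, list[_FittedModel]] = {}
        self.best_C_: dict[str, float] = {}
        self.fold_bac_: dict[str, float] = {}
        weight_rows = []
        for site, (train, test) in plan.outer_folds.items():
            ensemble, best_C = self._fit_outer(X, y, plan.inner_folds[site])
            self.models_[site] = ensemble
            self.best_C_[site] = best_C
            weight_rows.extend(m.coef for m in ensemble)
            scores = np.mean([m.decision(X[test]) for m in ensemble], axis=0)
            oof[test] = scores
            self.fold_bac_[site] = bac_score(y[test], (scores > 0).astype(int))
        self.weights_ = np.vstack(weight_rows)
        sites_arr = np.empty(n, dtype=object)
        for site, (_, test) in plan.outer_folds.items():
            sites_arr[test] = site
        self.oof_ = OOFScores(
            scores=oof, predicted=(oof > 0).astype(float), sites=sites_arr
        )
        self.classes_ = np.array([0, 1])
        return self

    def _fit_one(self, X, y, C) -> _FittedModel:
        median, mean, scale = _preprocess_fit(X)
        Z = _transform(X, median, mean, scale)
        w, b = _svm_fit(Z, y, C, self.max_iter)
        return _FittedModel(median, mean, scale, w, b)

    def _fit_outer(self, X, y, splits):
        """Grid-search C by mean inner-validation BAC; return the inner
        ensemble at the winning C (the models fitted during the search
        are reused — no refit). The training-split Gram matrix is
        shared across the whole C grid."""
        grid = list(self.C_grid)
        fitted: list[list[_FittedModel]] = [[] for _ in grid]
        bac = np.zeros((len(grid), len(splits)))
        for j, (itr, iva) in enumerate(splits):
            median, mean, scale = _preprocess_fit(X[itr])
            Ztr = _transform(X[itr], median, mean, scale)
            Zva = _transform(X[iva], median, mean, scale)
            gram = Ztr @ Ztr.T
            for i, C in enumerate(grid):
                w, b = _svm_fit(Ztr, y[itr], C, self.max_iter, gram=gram)
                fitted[i].append(_FittedModel(median, mean, scale, w, b))
                pred = (Zva @ w + b > 0).astype(int)
                bac[i, j] = bac_score(y[iva], pred)
        mean_bac = bac.mean(axis=1)
        best = int(np.argmax(mean_bac))  # argmax keeps the smallest C on ties
        return fitted[best], grid[best]

    def decision_function(self, X) -> np.ndarray:
        """Ensemble-mean decision values of all inner models (for external data)."""
        X = np.asarray(X, dtype=float)
        all_models = [m for ens in self.models_.values() for m in ens]
        return np.mean([m.decision(X) for m in all_models], axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_unimodal(cohort, modality: str, plan: FoldPlan | None = None, **learner_config):
    """Train one modality's nested-CV risk calculator on a cohort.

    Returns ``(estimator, OOFScores)``. Subjects whose block row is
    entirely missing are excluded from fitting and flagged NaN in the
    OOF scores.
    """
    if modality == "rater":
        raise ValueError("rater estimates are predictions, not a trainable block")
    if modality not in cohort.blocks:
        raise KeyError(f"cohort has no modality {modality!r}")
    X = np.asarray(cohort.blocks[modality], dtype=float)
    est = NestedLinearRiskCalculator(**learner_config)
    all_missing = np.isnan(X).all(axis=1)
    if all_missing.any():
        keep = ~all_missing
        sub_plan = plan
        if sub_plan is None:
            est.fit(X[keep], cohort.labels[keep], sites=cohort.sites[keep])
        else:
            raise ValueError(
                "cannot reuse a full-cohort FoldPlan when subjects are dropped; "
                "pass plan=None to rebuild folds on the retained subjects"
            )
        scores = np.full(len(cohort.labels), np.nan)
        pred = np.full(len(cohort.labels), np.nan)
        scores[keep] = est.oof_.scores
        pred[keep] = est.oof_.predicted
        oof = OOFScores(scores=scores, predicted=pred, sites=cohort.sites)
        return est, oof
    est.fit(X, cohort.labels, sites=cohort.sites, plan=plan)
    return est, est.oof_


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    n_permutations: int


def permutation_test(
    evaluate: Callable[[np.ndarray], float],
    labels,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of a cross-validated pipeline.

    ``evaluate`` must re-run the full nested CV for an arbitrary label
    vector and return its balanced accuracy. The p value uses the
    add-one convention p = (1 + #{null >= observed}) / (1 + B).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(labels, dtype=int)
    observed = float(evaluate(y))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = evaluate(rng.permutation(y))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return PermutationResult(observed=observed, null=null, p=float(p), n_permutations=n_permutations)
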