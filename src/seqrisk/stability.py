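"""Reliability and significance mapping of linear-model weights across CV folds.

Two per-feature summaries of the weight vectors collected over all
inner CV models:

* cross-validation ratio — mean weight divided by its standard error
  across models; a stability display metric (conventional display
  threshold |ratio| >= 3);
* sign-based consistency — exact two-sided binomial significance of
  the agreement of weight signs across models, converted to a z score
  and FDR-thresholded (z > 3.28 with adjusted p < .05 by default);
  this is the criterion used to condense a model to its significant
  features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .validation import train_unimodal

__all__ = [
    "FeatureStabilityMap",
    "cv_ratio",
    "sign_consistency_z",
    "fdr_adjust",
    "stability_map",
    "subsample_stability_weights",
    "condense_model",
]

#: z threshold corresponding to two-sided p ~ .001, the conventional cut.
DEFAULT_Z_THRESHOLD = 3.28


def cv_ratio(weights) -> np.ndarray:
    """Per-feature mean weight / standard error across CV models.

    ratio_j = mean_j / (sd_j / sqrt(M)). A zero standard error with a
    nonzero mean is flagged infinite (perfectly stable feature).
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("weights must be a (models x features) matrix with >= 2 models")
    m = W.shape[0]
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    se = sd / np.sqrt(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean / se
    ratio[(se == 0) & (mean == 0)] = 0.0
    ratio[(se == 0) & (mean != 0)] = np.inf * np.sign(mean[(se == 0) & (mean != 0)])
    return ratio


def sign_consistency_z(weights) -> tuple[np.ndarray, np.ndarray]:
    """Sign-based consistency of weights across CV models.

    For each feature, the count of strictly positive weights among the
    nonzero entries is tested against a fair coin with an exact
    two-sided binomial test; z is the standard-normal quantile at
    1 - p/2, so z > 3.28 corresponds to p < ~.001. Exact zeros carry
    no sign information and are excluded from the count; an all-zero
    column gets z = 0, p = 1 with a warning.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("weights must be a (models x features) matrix with >= 2 models")
    n_feat = W.shape[1]
    z = np.zeros(n_feat)
    p = np.ones(n_feat)
    for j in range(n_feat):
        col = W[:, j]
        nz = col[col != 0]
        if nz.size == 0:
            warnings.warn(f"feature {j} has all-zero weights; z set to 0", stacklevel=2)
            continue
        k = int((nz > 0).sum())
        p[j] = stats.binomtest(k, nz.size, 0.5, alternative="two-sided").pvalue
        # exact p can underflow for large M; cap the quantile argument
        q = min(1 - p[j] / 2, 1 - 1e-300)
        z[j] = stats.norm.ppf(q)
    return z, p


def fdr_adjust(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, rejection flags)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


@dataclass
class FeatureStabilityMap:
    """Per-feature stability and significance summary of a model ensemble."""

    mean_weight: np.ndarray
    cv_ratio: np.ndarray
    sign_z: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    selected: np.ndarray
    z_threshold: float
    alpha: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def stability_map(
    weights,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    alpha: float = 0.05,
) -> FeatureStabilityMap:
    """Full stability map: CV ratio, sign-consistency z, FDR, selection flags.

    A feature is selected when its sign-consistency z exceeds
    ``z_threshold`` and its FDR-adjusted p is below ``alpha``.
    """
    W = np.asarray(weights, dtype=float)
    z, p = sign_consistency_z(W)
    p_adj, reject = fdr_adjust(p, alpha=alpha)
    selected = (z > z_threshold) & reject
    return FeatureStabilityMap(
        mean_weight=W.mean(axis=0),
        cv_ratio=cv_ratio(W),
        sign_z=z,
        p_raw=p,
        p_fdr=p_adj,
        selected=selected,
        z_threshold=z_threshold,
        alpha=alpha,
    )


def subsample_stability_weights(
    X,
    y,
    n_models: int = 15,
    fraction: float = 0.1,
    C: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Weight ensemble for sign-consistency mapping, trained on small
    class-stratified random subsamples.

    The exact binomial sign test assumes the model votes are
    independent. Weight vectors from CV folds violate this badly: inner
    training sets share most of their subjects, so even a pure-noise
    feature keeps the sign of its full-sample weight across folds and
    the test becomes wildly anticonservative. Training each voting
    model on a small disjoint-ish subsample (default 10% of the cohort,
    pairwise overlap ~1%) makes the votes close to independent — a
    noise feature's sign is then dominated by subsample noise and
    near-unanimity is only reachable by genuine signal. This is the
    stability-selection compromise: small subsamples for selection,
    the full nested CV for fitting and evaluation.

    Returns an (n_models x n_features) weight matrix in standardized
    feature space.
    """
    from .validation import _preprocess_fit, _svm_fit, _transform

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    n_pos = max(3, int(round(fraction * pos.size)))
    n_neg = max(3, int(round(fraction * neg.size)))
    W = np.zeros((n_models, X.shape[1]))
    for m in range(n_models):
        idx = np.concatenate(
            [rng.choice(pos, n_pos, replace=False), rng.choice(neg, n_neg, replace=False)]
        )
        median, mean, scale = _preprocess_fit(X[idx])
        Z = _transform(X[idx], median, mean, scale)
        w, _ = _svm_fit(Z, y[idx], C, max_iter=20_000)
        W[m] = w
    return W


def condense_model(cohort, modality: str, stability: FeatureStabilityMap, plan=None, **learner_config):
    """Retrain the nested CV on the sign-consistency-selected features only.

    Selection is performed within the discovery data (the same cohort
    the weights came from), mirroring discovery-then-validate usage;
    the resulting optimism must be judged on held-back data. Returns
    ``(selected feature indices, estimator, OOFScores)``.
    """
    idx = np.flatnonzero(stability.selected)
    if idx.size == 0:
        raise ValueError(
            "no feature passed the sign-consistency selection; relax z_threshold "
            "or alpha before condensing"
        )
    reduced = _subset_cohort(cohort, modality, idx)
    est, oof = train_unimodal(reduced, modality, plan=plan, **learner_config)
    return idx, est, oof


def _subset_cohort(cohort, modality, idx):
    from .cohort import Cohort

    blocks = dict(cohort.blocks)
    blocks[modality] = cohort.blocks[modality][:, idx]
    return Cohort(
        subject_ids=cohort.subject_ids,
        blocks=blocks,
        sites=cohort.sites,
        labels=cohort.labels,
        rater_estimates=cohort.rater_estimates,
    )
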