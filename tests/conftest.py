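"""Shared fixtures: small synthetic cohorts and fold plans.

Cohort sizes are scaled down from the full 334-subject default where a
test only exercises machinery, to keep the suite fast; tests that
check cohort realism use the full default configuration.
"""

import warnings

import numpy as np
import pytest

from seqrisk import CohortConfig, generate_cohort, make_losocv_folds


SMALL_CONFIG = dict(
    n_per_site=(40, 30, 30),
    n_transitions=12,
    transitions_per_site=(5, 4, 3),
    block_dims={"clinical": 20, "prs": 5, "smri": 25},
    n_informative={"clinical": 6, "prs": 5, "smri": 10},
    effect_size={"clinical": 1.2, "prs": 0.5, "smri": 0.5},
    missing_rate={},
)

FAST_LEARNER = dict(n_inner_folds=4, C_grid=(0.01, 0.1, 1.0, 10.0))


def small_cohort(seed=0, **overrides):
    cfg = {**SMALL_CONFIG, **overrides, "seed": seed}
    return generate_cohort(CohortConfig(**cfg))


@pytest.fixture
def cohort_small():
    return small_cohort(seed=3)


@pytest.fixture
def plan_small(cohort_small):
    return make_losocv_folds(cohort_small.sites, cohort_small.labels, n_inner_folds=4, seed=3)


@pytest.fixture
def default_cohort():
    """Full-size default cohort (334 subjects, 7 sites, 26 events)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class-site warning (Udine)
        return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
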