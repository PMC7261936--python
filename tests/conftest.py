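"""Shared fixtures: synthetic cohorts and their feature tables.

Cohort generation is the slowest step, so the full-size tables are built
once per session and shared by the evaluation/acceptance tests.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from spastiq.pipeline import build_feature_table
from spastiq.synth import CohortSpec, iter_cohort


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    """The study-scale cohort: 15 subjects (4/3/5/3 across MAS 0/1/1+/2)."""
    return CohortSpec(master_seed=0)


@pytest.fixture(scope="session")
def fast_tables(default_spec):
    """(window_table, trial_table, truth) for the fast stretches of the cohort."""
    truth_rows = []

    def trials():
        for rec, truth in iter_cohort(default_spec, velocity_classes=("fast",)):
            truth_rows.append(truth)
            yield rec

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        window_table, trial_table = build_feature_table(trials())
    return window_table, trial_table, pd.DataFrame(truth_rows)


@pytest.fixture(scope="session")
def allclass_tables():
    """Feature/trial tables over all three velocity classes (2 trials each)."""
    spec = CohortSpec(master_seed=0, trials_per_class={"slow": 2, "normal": 2, "fast": 2})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(r for r, _ in iter_cohort(spec))


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """A four-subject, fast-only cohort for smoke tests."""
    return CohortSpec(
        n_per_level={0.0: 1, 1.0: 1, 1.5: 1, 2.0: 1},
        trials_per_class={"slow": 0, "normal": 0, "fast": 2},
        master_seed=3,
    )


@pytest.fixture(scope="session")
def tiny_tables(tiny_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(r for r, _ in iter_cohort(tiny_spec))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
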