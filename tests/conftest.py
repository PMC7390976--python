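import warnings

import numpy as np
import pandas as pd
import pytest

from cardiocast import SyntheticConfig, generate_cohort
from cardiocast.features import FeatureTable, OUTCOME_COLUMN


@pytest.fixture(scope="session")
def small_cohort():
    """20 synthetic runs with default planted effects (session-cached)."""
    config = SyntheticConfig(n_runs=20, seed=5)
    runs, gt = generate_cohort(config)
    return config, runs, gt


@pytest.fixture(scope="session")
def complete_run(small_cohort):
    _, runs, _ = small_cohort
    return runs[0]


@pytest.fixture(scope="session")
def cohort_table(small_cohort):
    from cardiocast import build_feature_table

    _, runs, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(runs, cutoff="dd7")


def make_table(X, y=None, run_ids=None, columns=None):
    """Small helper to build FeatureTables from raw arrays in tests."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    run_ids = run_ids or [f"r{i}" for i in range(n)]
    columns = columns or [f"do_mean_dd{j}" for j in range(d)]
    data = pd.DataFrame(X, index=run_ids, columns=columns)
    outcome = None
    if y is not None:
        outcome = pd.Series(np.asarray(y, dtype=float), index=run_ids, name=OUTCOME_COLUMN)
    return FeatureTable(data, outcome)
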