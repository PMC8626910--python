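import numpy as np
import pandas as pd
import pytest

import csfpanel as cp


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset (matrix, annotations, truth), normalized."""
    cohort = cp.generate_cohort(cp.CohortSpec(seed=11))
    matrix, samples, truth = cp.generate_assay(
        cohort, cp.EffectSpec(), cp.AssaySpec(), seed=11)
    norm = cp.plate_normalize(
        cp.drift_normalize(matrix, samples["readout_order"]), samples["plate"])
    return norm, samples, truth


@pytest.fixture(scope="session")
def affected_xy(default_dataset):
    """Feature matrix and labels for the affected-vs-unaffected comparison."""
    matrix, samples, _ = default_dataset
    sel = cp.select_comparison_cohort(samples, cp.ComparisonConfig())
    X = matrix.loc[sel["sample_id"]]
    return X, sel["label"].to_numpy()


@pytest.fixture(scope="session", autouse=True)
def _warm_engines():
    """Trigger numba compilation once so individual tests time cleanly."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 5))
    y = (rng.random(30) < 0.5).astype(int)
    y[:3] = 1
    y[3:6] = 0
    cp.single_forest(X, y, cp.ForestConfig(n_trees=5), seed=0,
                     warn_degenerate=False)
    cp.cv_lasso_fit(X, y, cp.LassoConfig(n_lambdas=10), cv_seed=0)
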