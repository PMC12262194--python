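import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bifurcgrn as bg
from bifurcgrn import pipeline

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("bifurcgrn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def truth():
    return bg.generate_true_grn(n_tf=8, n_gene=30, n_cre_per_gene=5, seed=11)


@pytest.fixture(scope="session")
def dataset(truth):
    return bg.simulate_multiome(truth, n_cells=600, seed=12)


@pytest.fixture(scope="session")
def dataset_frames(dataset):
    return pipeline.frames(dataset)


@pytest.fixture(scope="session")
def norm_expr(dataset_frames):
    expr, _, _ = dataset_frames
    return bg.normalize_expression(expr)


@pytest.fixture(scope="session")
def state_labels(dataset):
    return pd.Series(
        dataset.cells["state"].to_numpy(), index=dataset.cells["cell"].to_numpy()
    )


@pytest.fixture(scope="session")
def truth_base_grn(truth):
    return pipeline.base_grn_from_truth(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
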