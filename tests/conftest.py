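"""Shared fixtures: a small synthetic landscape and a fitted forest.

Session-scoped so the forest is fitted once; tests that mutate state
build their own objects.
"""

import numpy as np
import pytest

from srscape.forest import IsoscapeForest
from srscape.grid import GridSpec, extract_predictors
from srscape.synthetic import SyntheticConfig, make_landscape, sample_sites


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_rows=40, n_cols=40, n_samples=150, n_individuals=20, seed=1)


@pytest.fixture(scope="session")
def landscape(small_config):
    return make_landscape(small_config)


@pytest.fixture(scope="session")
def samples(small_config, landscape):
    _, truth = landscape
    return sample_sites(truth, small_config.n_samples, small_config.within_cell_sd, seed=2)


@pytest.fixture(scope="session")
def design(samples, landscape):
    stack, _ = landscape
    return extract_predictors(samples, stack)


@pytest.fixture(scope="session")
def sr_response(samples):
    return samples.frame["sr_ratio"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def forest(design, sr_response):
    model = IsoscapeForest(n_trees=120, categorical=["lithology"], random_state=3)
    model.fit(design.predictors(), sr_response)
    return model


@pytest.fixture()
def flat_spec():
    """A small projected grid where cell-centre distances are Euclidean."""
    return GridSpec(n_rows=6, n_cols=6, x_min=0.0, y_max=6.0, cell_size=1.0, crs="local-metres")


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
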