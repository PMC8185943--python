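"""Shared simulation fixtures (session-scoped: several tests reuse the
same calibrated fits to keep the suite fast)."""

import numpy as np
import pytest

from isqkit.cfa import OrdinalFactorModel
from isqkit.grm import GradedResponseModel
from isqkit.polychoric import bootstrap_polychoric, polychoric_matrix
from isqkit.simulate import (SimConfig, default_items, simulate_responses,
                             study_like_config)


@pytest.fixture(scope="session")
def items8():
    """Clean 8-item, 7-category bank with slopes in [1, 2.5]."""
    return default_items(8, 7, seed=3)


@pytest.fixture(scope="session")
def grm8_sim(items8):
    cfg = SimConfig(items=items8, n_per_group={"g": 2000}, seed=4)
    return simulate_responses(cfg)


@pytest.fixture(scope="session")
def grm8_fit(grm8_sim):
    X, _ = grm8_sim
    return GradedResponseModel(X).fit()


@pytest.fixture(scope="session")
def cfa8_model(grm8_sim):
    X, _ = grm8_sim
    return OrdinalFactorModel.from_data(X, n_boot=100, seed=5)


@pytest.fixture(scope="session")
def cfa8_results(cfa8_model):
    return cfa8_model.fit()


@pytest.fixture(scope="session")
def study_sim():
    """Default study conditions: 20 items, two cohorts, six doublets."""
    return simulate_responses(study_like_config(seed=7))


@pytest.fixture(scope="session")
def study_R(study_sim):
    X, _ = study_sim
    return polychoric_matrix(X)


@pytest.fixture(scope="session")
def study_boot(study_sim):
    X, _ = study_sim
    return bootstrap_polychoric(X, n_boot=80, seed=7)
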