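"""Shared fixtures: surrogate data-sets and a session-wide trained stack."""

import pytest

from dropforge.physics import DesignPoint
from dropforge.predictor import TrainingConfig, train_stack
from dropforge.synthetic import (
    SurrogateParams,
    SurrogatePredictor,
    generate_dataset,
)


@pytest.fixture(scope="session")
def surrogate_params() -> SurrogateParams:
    return SurrogateParams()


@pytest.fixture(scope="session")
def records600(surrogate_params):
    """600 noisy surrogate observations — the default training data-set."""
    return generate_dataset(600, surrogate_params, seed=1)


@pytest.fixture(scope="session")
def trained_stack(records600, surrogate_params):
    """One stack trained on the 600-point set, shared across the session."""
    return train_stack(records600, TrainingConfig(seed=0),
                       fluids=surrogate_params.fluids)


@pytest.fixture(scope="session")
def surrogate_predictor(surrogate_params) -> SurrogatePredictor:
    """The surrogate wrapped as a perfect predictor."""
    return SurrogatePredictor(surrogate_params)


@pytest.fixture(scope="session")
def nominal_design() -> DesignPoint:
    """An interior design point away from all sampling-range boundaries."""
    return DesignPoint.from_vector([150.0, 2.0, 2.5, 3.0, 3.0, 2.0, 0.1, 10.0])
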