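import numpy as np
import pytest

from emels import (
    LongitudinalDataset,
    QuadratureRule,
    Theta,
    simulate_emels,
)


@pytest.fixture(scope="session")
def toy_theta():
    return Theta.from_phi([1.0, 0.3], -0.5, 0.2, np.diag([0.8, 0.3, 0.3]))


@pytest.fixture(scope="session")
def toy_dataset(toy_theta):
    """Small location-scale sample: 8 persons x 6 occasions, one slope."""
    ds, _ = simulate_emels(I=8, T=6, beta=toy_theta.beta, s0=toy_theta.s0,
                           r0=toy_theta.r0, phi=toy_theta.phi, seed=42)
    return ds

@pytest.fixture(scope="session")
def two_person_toy(toy_dataset):
    return LongitudinalDataset(toy_dataset.series[:2],
                               toy_dataset.predictor_names)


@pytest.fixture(scope="session")
def rule_q5():
    return QuadratureRule.gauss_hermite(5, 3)


@pytest.fixture(scope="session")
def rule_q4():
    return QuadratureRule.gauss_hermite(4, 3)
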