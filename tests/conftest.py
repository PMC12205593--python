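import numpy as np
import pytest

from twentyone.dcmd import DCMDParams
from twentyone.synth import CohortSpec, sample_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six DC-MD agents playing the full behavioral protocol."""
    params, sessions = sample_cohort(CohortSpec(n_participants=6, seed=11))
    return params, sessions


@pytest.fixture(scope="session")
def tiny_sessions():
    """Two agents, three games each — fast smoke-test data."""
    _, sessions = sample_cohort(CohortSpec(n_participants=2, seed=5, n_games=3))
    return sessions


@pytest.fixture
def moderate_params():
    """A hand-picked, well-behaved DC-MD parameter set."""
    return DCMDParams(
        beta_k=[0.0, 1.5],
        beta_ck=[-2.0, 0.4, 1.5],
        epsilon=0.9,
        gamma=0.25,
        beta_i=[0.2, 0.9, 0.2],
        beta_ci=[-1.5, 0.5, 1.5],
        sigma_k=0.15,
        sigma_i=0.15,
        theta_k=[0.3, 0.5, 0.7],
        theta_i=[0.3, 0.5, 0.7],
    )


@pytest.fixture
def sharp_params():
    """Near-deterministic DC-MD parameters (saturated read-outs)."""
    return DCMDParams(
        beta_k=[0.0, 50.0],
        beta_ck=[-10.0, 5.0, 5.0],
        epsilon=0.999,
        gamma=0.0,
        beta_i=[0.0, 50.0, 0.0],
        beta_ci=[-20.0, 10.0, 0.0],
        sigma_k=0.02,
        sigma_i=0.02,
        theta_k=[0.3, 0.5, 0.7],
        theta_i=[0.3, 0.5, 0.7],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
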