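import numpy as np
import pytest

from twostep import Parameters, SessionData, TaskConfig


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def short_config():
    return TaskConfig(n_trials=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_session(first_choice, second_state, second_choice, reward, subject_id="s", **kw):
    return SessionData(
        subject_id=subject_id,
        first_choice=np.asarray(first_choice),
        second_state=np.asarray(second_state),
        second_choice=np.asarray(second_choice),
        reward=np.asarray(reward),
        **kw,
    )


def random_session(rng, n_trials=12, subject_id="s"):
    return make_session(
        rng.integers(0, 2, n_trials),
        rng.integers(0, 2, n_trials),
        rng.integers(0, 2, n_trials),
        rng.integers(0, 2, n_trials),
        subject_id=subject_id,
    )


def random_parameters(rng):
    return Parameters(
        alpha1=rng.uniform(0.05, 0.95),
        alpha2=rng.uniform(0.05, 0.95),
        lam=rng.uniform(0.05, 0.95),
        omega=rng.uniform(0.05, 0.95),
        beta1=rng.uniform(0.1, 12.0),
        beta2=rng.uniform(0.1, 12.0),
        rho=rng.normal(0.0, 0.3),
    )
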