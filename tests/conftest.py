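import numpy as np
import pytest

from matechoice import ModelParams, Tradeoff

UNIFORM = np.full(4, 0.25)


@pytest.fixture
def fig1_params() -> ModelParams:
    """Guarding trade-off, neutral-line regime (published panel values)."""
    return ModelParams(a=1.0, e=0.8, delta_e=0.7, theta=0.8, delta_theta=0.1,
                       tradeoff=Tradeoff.GUARDING)


@pytest.fixture
def fig2a_params() -> ModelParams:
    """Care trade-off with the preference-persistence condition violated."""
    return ModelParams(a=1.5, e=0.8, delta_e=0.1, theta=0.8, delta=0.1, b=0.8,
                       tradeoff=Tradeoff.CARE)


@pytest.fixture
def fig2b_params() -> ModelParams:
    """Care trade-off with the preference-persistence condition met."""
    return ModelParams(a=1.5, e=0.8, delta_e=0.8, theta=0.8, delta=0.1, b=0.8,
                       tradeoff=Tradeoff.CARE)


def random_params(rng: np.random.Generator) -> ModelParams:
    """A random valid parameter set spanning both trade-off variants."""
    theta = rng.uniform(0.2, 0.99)
    tradeoff = Tradeoff.GUARDING if rng.random() < 0.5 else Tradeoff.CARE
    return ModelParams(
        a=rng.uniform(0.0, 3.0),
        theta=theta,
        delta_theta=rng.uniform(0.0, 0.9 * theta),
        e=rng.uniform(0.1, 2.0),
        delta_e=rng.uniform(0.0, 1.0),
        b=rng.uniform(0.0, 2.0),
        delta=rng.uniform(0.0, 1.0),
        s_f=rng.uniform(0.0, 0.5),
        s_m=rng.uniform(0.0, 0.5),
        r=rng.uniform(0.0, 0.5),
        tradeoff=tradeoff,
    )


def random_state(rng: np.random.Generator) -> np.ndarray:
    x = rng.dirichlet(np.ones(4))
    return x / x.sum()
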