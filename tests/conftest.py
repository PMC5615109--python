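import numpy as np
import pytest

from dsia import RegimeParameters, SwitchingModel, validate_generator


def make_params(rng, n, sigma_scale=0.3):
    """One random parameter regime with rates in the documented ranges."""
    beta = rng.uniform(0.05, 1.0)
    alpha = rng.uniform(0.5, 3.0, n)
    return RegimeParameters(
        mu=rng.uniform(0.05, 1.0),
        gamma=rng.uniform(0.05, 1.0),
        beta=beta,
        S0=rng.uniform(10.0, 200.0, n),
        alpha=alpha,
        sigma=sigma_scale * np.sqrt(beta * alpha) * rng.uniform(0.5, 1.0, n),
    )


def make_generator(rng, L):
    if L == 1:
        return validate_generator([[0.0]])
    off = rng.uniform(0.05, 1.0, (L, L))
    np.fill_diagonal(off, 0.0)
    return validate_generator(off - np.diag(off.sum(axis=1)))


def make_model(rng, n=2, L=2, sigma_scale=0.3):
    return SwitchingModel(
        generator=make_generator(rng, L),
        regimes=tuple(make_params(rng, n, sigma_scale) for _ in range(L)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_regime_model(rng):
    return make_model(rng, n=2, L=2)


@pytest.fixture
def single_regime_params():
    """Deterministic-friendly single regime with R0 = 2."""
    return RegimeParameters(
        mu=0.1, gamma=0.15, beta=0.5, S0=[100.0], alpha=[1.0], sigma=[0.0]
    )
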