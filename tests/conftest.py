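import numpy as np
import pytest

from omegaperf import CensoringScheme, OmegaParams, draw_progressive_sample, quantile


@pytest.fixture(scope="session")
def running_params():
    """The fitted HPLC triple used throughout the conforming-rate table."""
    return OmegaParams(4.28, 2.61, 57.79)


@pytest.fixture(scope="session")
def synth_params():
    """Moderate-exponent triple used for synthetic studies."""
    return OmegaParams(2.0, 1.5, 10.0)


@pytest.fixture(scope="session")
def small_exponent_params():
    """Small survival exponent: the bounded support is clearly visible."""
    return OmegaParams(0.5, 0.8, 5.0)


def complete_scheme(n):
    return CensoringScheme(n, n, (0,) * n)


@pytest.fixture(scope="session")
def draw_complete():
    def _draw(params, n, seed):
        return draw_progressive_sample(
            complete_scheme(n), lambda u: quantile(u, params), seed=seed
        )

    return _draw


def random_valid_params(rng, beta_range=(0.3, 5.0), log_a_range=(0.0, 13.8)):
    """Random parameter triple with survival exponent a in [1, ~1e6]."""
    beta = rng.uniform(*beta_range)
    gamma_ = rng.uniform(0.5, 50.0)
    a = np.exp(rng.uniform(*log_a_range))
    alpha = 2.0 * a / gamma_**beta
    return OmegaParams(alpha, beta, gamma_)
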