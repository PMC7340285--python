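import numpy as np
import pandas as pd
import pytest

from whalekrill import glm, synthetic


@pytest.fixture(scope="session")
def small_grid():
    return synthetic.make_study_grid((18.0, 18.0), 1.0)


@pytest.fixture(scope="session")
def survey_bins(small_grid):
    """A modest multi-cruise synthetic survey shared across tests."""
    cruises = synthetic.make_cruise_calendar(8, seed=11)
    truth = synthetic.TruthSpec.default(seed=11)
    bins = synthetic.simulate_observations(small_grid, cruises, truth, seed=12)
    return bins, truth


def make_nb_frame(seed: int, n: int, beta=(1.0, 0.5), theta: float = 2.0,
                  x_mean: float = 0.0, x_sd: float = 1.0) -> pd.DataFrame:
    """NB2 regression data y ~ NB(exp(b0 + b1 x), theta)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(x_mean, x_sd, size=n)
    mu = np.exp(beta[0] + beta[1] * x)
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.DataFrame({"x": x, "y": y})


def make_hurdle_frame(seed: int, n: int, gamma=(-0.5, 1.0), beta=(2.0, 0.8),
                      theta: float = 1.5) -> pd.DataFrame:
    """Hurdle data: presence logit(g0 + g1 x), positives ZTNB."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    p = 1.0 / (1.0 + np.exp(-(gamma[0] + gamma[1] * x)))
    present = rng.uniform(size=n) < p
    mu = np.exp(beta[0] + beta[1] * x)
    y = np.zeros(n, dtype=int)
    y[present] = synthetic.sample_ztnb(mu[present], theta, rng)
    return pd.DataFrame({"x": x, "y": y})


def nb_design(response: str = "y") -> glm.DesignSpec:
    return glm.DesignSpec(response, [glm.Term("x")])
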