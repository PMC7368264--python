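import numpy as np
import pytest

import matage
from matage.vital_rates import VitalRates


@pytest.fixture(scope="session")
def default_vital() -> VitalRates:
    return matage.default_vital_rates()


@pytest.fixture(scope="session")
def default_model(default_vital):
    return matage.build(default_vital)


@pytest.fixture(scope="session")
def default_eigen(default_model):
    return matage.eigen(default_model)


@pytest.fixture(scope="session")
def scenario_set(default_vital):
    return matage.build_scenarios(default_vital)


@pytest.fixture(scope="session")
def tiny_vital() -> VitalRates:
    """Hand-sized 2x2 table whose block matrix is fully checkable by eye."""
    return VitalRates(s=2, omega=2, p=[[0.5, 0], [0.4, 0]],
                      f=[[2, 1], [1.5, 0.5]])


def random_vital(seed: int, s: int = 16, omega: int = 16) -> VitalRates:
    """A random plausible vital-rate table (growing population, late-age
    fertility decline) for property tests."""
    rng = np.random.default_rng(seed)
    ages = np.arange(1, omega + 1)
    p = np.clip(rng.uniform(0.55, 0.99, size=(s, omega))
                * np.exp(-0.01 * ages ** 1.5)[None, :], 0.0, 1.0)
    p[:, -1] = 0.0
    peak = rng.uniform(3, 6)
    n = 4.0 * np.exp(-0.5 * ((ages - peak) / 2.0) ** 2)
    n[ages < 2] = 0.0
    f = n[None, :] * rng.uniform(0.6, 1.0, size=(s, omega))
    return VitalRates(s=s, omega=omega, p=p, f=f)
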