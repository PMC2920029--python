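import numpy as np
import pytest

from mesoproj import MortalitySurface, ParameterSet, reference_parameters
from mesoproj.exposure import GrowthRateKnots
from mesoproj import synthetic as syn


@pytest.fixture(scope="session")
def truth() -> ParameterSet:
    return reference_parameters()


@pytest.fixture(scope="session")
def population() -> MortalitySurface:
    """Default smooth population surface, ages 20-89 x years 1968-2050."""
    return syn.make_population()


@pytest.fixture(scope="session")
def c_true(truth, population) -> float:
    return syn.calibrate_scale(truth, population)


@pytest.fixture(scope="session")
def synthetic_data(truth, population, c_true) -> MortalitySurface:
    """One realisation of the death surface at the reference truth (seed 1)."""
    data, _ = syn.simulate_deaths(truth, population, c_true, seed=1)
    return data


@pytest.fixture
def flat_knots() -> GrowthRateKnots:
    """All estimated and fixed rates zero: a flat exposure history."""
    return GrowthRateKnots({o: 0.0 for o in (-65, -55, -45, -35, -25, -15, -5, 5, 15)})


@pytest.fixture
def toy_surface() -> MortalitySurface:
    """Tiny 5-age x 5-year surface for loop-oracle comparisons."""
    rng = np.random.default_rng(42)
    ages = np.arange(30, 35)
    years = np.arange(1990, 1995)
    P = rng.uniform(1e4, 1e5, size=(5, 5))
    Y = rng.poisson(5.0, size=(5, 5))
    return MortalitySurface(ages=ages, years=years, person_years=P, deaths=Y)
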