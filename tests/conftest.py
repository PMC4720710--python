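import numpy as np
import pytest

from pcbayes import (
    PeriodGrid,
    TimeGrid,
    benchmark_experiment,
    build_dictionary,
)


@pytest.fixture(scope="session")
def circadian_grid():
    return PeriodGrid.circadian()


@pytest.fixture(scope="session")
def hourly96():
    return TimeGrid.hourly(96)


@pytest.fixture(scope="session")
def dict_summed(hourly96, circadian_grid):
    return build_dictionary(hourly96, circadian_grid, basis="summed")


@pytest.fixture(scope="session")
def dict_split(hourly96, circadian_grid):
    return build_dictionary(hourly96, circadian_grid, basis="split")


@pytest.fixture(scope="session")
def exp_5db():
    """The standard 4-day experiment at 5 dB, one fixed realization."""
    return benchmark_experiment(snr_db=5.0, seed=0)


@pytest.fixture(scope="session")
def exp_15db():
    return benchmark_experiment(snr_db=15.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
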