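import numpy as np
import pytest

from lifespans import SurvivalDataset
from lifespans.simulate import SimulationSpec, simulate_lifespans


def random_dataset(rng, n_max=12, label="r", censoring=True, integer_times=True):
    """Small random grouped dataset with at least one death."""
    n = int(rng.integers(3, n_max + 1))
    if integer_times:
        times = rng.integers(1, 15, size=n).astype(float)
    else:
        times = np.round(rng.uniform(0.5, 20.0, size=n), 3)
    status = rng.integers(0, 2, size=n) if censoring else np.ones(n, dtype=int)
    if status.sum() == 0:
        status[rng.integers(0, n)] = 1
    return SurvivalDataset.from_subjects(label, times, status)


def gaussian_pair(seed, n=100, mean1=20.0, sd1=4.0, mean2=20.0, sd2=4.0):
    """Two independent integer-day Gaussian-lifespan cohorts."""
    ss = np.random.SeedSequence(seed).spawn(2)
    a = simulate_lifespans(
        SimulationSpec("gaussian", {"mean": mean1, "sd": sd1}, n=n, label="g1"),
        seed=int(np.random.default_rng(ss[0]).integers(2**31)),
    )
    b = simulate_lifespans(
        SimulationSpec("gaussian", {"mean": mean2, "sd": sd2}, n=n, label="g2"),
        seed=int(np.random.default_rng(ss[1]).integers(2**31)),
    )
    return a, b


def exponential_pair(seed, n=50, rate1=0.05, rate2=0.05):
    ss = np.random.SeedSequence(seed).spawn(2)
    a = simulate_lifespans(
        SimulationSpec("exponential", {"rate": rate1}, n=n, label="e1"),
        seed=int(np.random.default_rng(ss[0]).integers(2**31)),
    )
    b = simulate_lifespans(
        SimulationSpec("exponential", {"rate": rate2}, n=n, label="e2"),
        seed=int(np.random.default_rng(ss[1]).integers(2**31)),
    )
    return a, b


@pytest.fixture
def simple_ds():
    """4 subjects: deaths at 10 and 20, two censored at 30."""
    return SurvivalDataset.from_records("simple", [(10, 1, 0), (20, 1, 0), (30, 0, 2)])


@pytest.fixture
def uncensored_ds():
    return SurvivalDataset.from_records("unc", [(18, 1, 0), (20, 1, 0), (22, 1, 0)])
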