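import numpy as np
import pytest

from gametherm import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sand_dollar_design():
    return synthetic.sand_dollar_design()


@pytest.fixture
def default_truth():
    return synthetic.default_truth(seed=7)


@pytest.fixture
def single_factor_data(sand_dollar_design, default_truth):
    return synthetic.generate_single_factor_assay(sand_dollar_design, default_truth)


@pytest.fixture
def factorial_data(default_truth):
    design = synthetic.factorial_design()
    return synthetic.generate_factorial_assay(design, default_truth)


def gaussian_probability(temp, rmax=0.95, topt=17.6, width=7.0):
    """Truth curve used by recovery/coverage simulations in several tests."""
    temp = np.asarray(temp, dtype=float)
    return np.clip(rmax * np.exp(-0.5 * ((temp - topt) / width) ** 2), 0.0, 1.0)


def simulate_binomial_tpc(seed, temps=synthetic.SAND_DOLLAR_TEMPERATURES,
                          n_pairs=3, eggs=150, **truth_kw):
    """(temperature, proportion) replicate data: binomial counts around a
    gaussian TPC — the generating process for parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    t = np.repeat(temps, n_pairs)
    p = gaussian_probability(t, **truth_kw)
    rate = rng.binomial(eggs, p) / eggs
    return t, rate
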