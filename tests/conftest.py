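import numpy as np
import pandas as pd
import pytest

import killwinner as kw


@pytest.fixture(scope="session")
def tradeoff_traits():
    """Ground-truth traits with the default (Table-1-scale) trade-off."""
    return kw.draw_traits(40, seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset(tradeoff_traits):
    """Exact-proportions, noise-free dilution experiment: every downstream
    estimate is analytically predictable from the traits."""
    design = kw.ExperimentDesign(exact_proportions=True, density_cv=0.0, seed=11)
    return kw.simulate_experiment(design, tradeoff_traits, experiment="exp1")


@pytest.fixture(scope="session")
def noisy_dataset(tradeoff_traits):
    """Default observation model: multinomial reads at depth 3188, 5% CV densities."""
    return kw.simulate_experiment(kw.ExperimentDesign(seed=11), tradeoff_traits)


@pytest.fixture(scope="session")
def noiseless_rates(noiseless_dataset):
    return kw.estimate_rates(noiseless_dataset)


@pytest.fixture(scope="session")
def noisy_rates(noisy_dataset):
    return kw.estimate_rates(noisy_dataset)


def brute_force_ols(x, y):
    """Normal-equations oracle for simple linear regression."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def brute_force_pearson(x, y):
    """Covariance-formula oracle for Pearson's r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum())
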