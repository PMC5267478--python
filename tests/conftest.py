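"""Shared fixtures: frozen parameter sets, synthetic data, posterior chains.

The MCMC chains are expensive (minutes each), so they are session-scoped and
shared between the calibration, classification and acceptance tests.
"""

import numpy as np
import pytest

from mapkqb.bayes import mcmc_sample
from mapkqb.classify import population_classify
from mapkqb.model import ParamVec
from mapkqb.synth import default_design, generate_dataset, load_fixture

MCMC_STEPS = 20_000
MCMC_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def theta_B() -> ParamVec:
    return load_fixture("theta_B")


@pytest.fixture(scope="session")
def theta_Q() -> ParamVec:
    return load_fixture("theta_Q")


@pytest.fixture(scope="session")
def theta_M() -> ParamVec:
    return load_fixture("theta_M")


@pytest.fixture(scope="session")
def dataset():
    """Synthetic calibration dataset from the quasi-bistable ground truth."""
    return generate_dataset(default_design(seed=0))


@pytest.fixture(scope="session")
def chains(dataset):
    """Posterior chains for three seeds on the shared synthetic dataset."""
    return {seed: mcmc_sample(dataset, n_steps=MCMC_STEPS, seed=seed)
            for seed in MCMC_SEEDS}


@pytest.fixture(scope="session")
def posterior(chains):
    """The first chain: the synthetic posterior used by population analyses."""
    return chains[MCMC_SEEDS[0]]


@pytest.fixture(scope="session")
def per_draw_classification(posterior):
    """Per-draw trajectory labels + rest-state CBA classes for the posterior."""
    fractions, per_draw = population_classify(posterior)
    return fractions, per_draw


def search_box_draws(seed: int, n: int):
    """Random parameter sets from the physiological search box (test oracle inputs)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rates = 10.0 ** rng.uniform(np.log10(0.05), np.log10(20.0), size=8)
        kf = 10.0 ** rng.uniform(np.log10(0.1), np.log10(50.0), size=2)
        g = rng.uniform(2.0, 6.0)
        K = 10.0 ** rng.uniform(np.log10(2.0), np.log10(30.0))
        out.append(ParamVec.from_array(np.concatenate([rates, kf, [g, K]])))
    return out
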