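"""Shared fixtures: small seeded cohorts generated at test time."""

import numpy as np
import pytest

import cpmshrink as cs


@pytest.fixture(scope="session")
def scenario5_population():
    """Moderate population from scenario 5's generating mechanism."""
    return cs.generate_population(cs.scenario(5, n_population=20_000, seed=42))


@pytest.fixture(scope="session")
def dev898(scenario5_population):
    """A development cohort at the scenario-5 minimum sample size (n=898)."""
    dev, _ = cs.split_development(scenario5_population, 898, 7)
    return dev


@pytest.fixture(scope="session")
def toy_cohort():
    """n=200 cohort with one strong predictor (for direct-evaluation oracles)."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(200)
    from scipy.special import expit

    y = (rng.random(200) < expit(-0.5 + 1.2 * x)).astype(float)
    return cs.Cohort(X=x[:, None], y=y)
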