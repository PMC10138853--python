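import numpy as np
import pandas as pd
import pytest

from healthineq import fractional_rank
from healthineq.synthetic import GeneratorConfig


@pytest.fixture
def four_unit_ranked():
    """Four untied units with equal weights: ranks 1/8, 3/8, 5/8, 7/8."""
    return fractional_rank(["a", "b", "c", "d"], np.ones(4))


@pytest.fixture
def small_config():
    """A small but fully structured two-survey generator configuration."""
    return GeneratorConfig(
        n_surveys=2,
        survey_years=(2011, 2016),
        strata_per_survey=6,
        clusters_per_stratum=5,
        women_per_cluster=15,
        superpopulation_n=50_000,
        seed=42,
    )


def random_binary_fixture(rng, max_n=500, n_levels=3):
    """A random weighted sample on an ordinal stratifier with a binary
    outcome guaranteed non-degenerate (both outcome values, >= 2 categories)."""
    while True:
        n = int(rng.integers(10, max_n + 1))
        strat = rng.integers(0, n_levels, size=n)
        h = rng.binomial(1, rng.uniform(0.1, 0.9), size=n).astype(float)
        w = rng.uniform(0.1, 3.0, size=n)
        if np.unique(strat).size >= 2 and 0 < h.sum() < n:
            return strat, h, w


@pytest.fixture
def fixture_factory():
    return random_binary_fixture
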