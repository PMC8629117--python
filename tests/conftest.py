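import numpy as np
import pytest

import phenocue as pc


@pytest.fixture(scope="session")
def scenario():
    """The bundled default scenario: 55 years, planted mean-cue 81..14."""
    climate, pheno, truth = pc.default_scenario(seed=0)
    return climate, pheno, truth


@pytest.fixture(scope="session")
def scenario_matrix(scenario):
    climate, pheno, _ = scenario
    return pc.build_climate_matrix(climate, pheno.years)


@pytest.fixture(scope="session")
def toy_matrix():
    """Small deterministic matrix (6 years x 10 lags) for oracle checks."""
    rng = np.random.default_rng(7)
    years = np.arange(2000, 2006)
    lags = np.arange(10)
    values = rng.normal(8.0, 2.0, size=(6, 10))
    return pc.ClimateMatrix(years, lags, values)


@pytest.fixture(scope="session")
def toy_phenology(toy_matrix):
    rng = np.random.default_rng(8)
    # event day loosely driven by mean of lags 2..5 plus noise
    cue = toy_matrix.values[:, 2:6].mean(axis=1)
    days = np.asarray(np.rint(60 - 3.0 * cue + rng.normal(0, 1.5, 6)), dtype=int)
    return pc.PhenologySeries(toy_matrix.years, days)
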