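"""Shared fixtures: one synthetic study system reused across the suite."""

import warnings

import pytest

import tevtrade as tt
from tevtrade.synthgen import (generate_econ_tables, generate_landscape,
                               generate_valuation_dataset)

warnings.filterwarnings("ignore", category=UserWarning)

#: generative terms used throughout (the default true model)
TRUE_TERMS = ("es_class", "method_class", "temperature", "year", "richness_birds")


@pytest.fixture(scope="session")
def base_cfg():
    return tt.SynthConfig(grid_nx=20, grid_ny=20, n_countries=4,
                          n_records=78, rng_seed=7)


@pytest.fixture(scope="session")
def grid(base_cfg):
    return generate_landscape(base_cfg)


@pytest.fixture(scope="session")
def records_truth(base_cfg, grid):
    return generate_valuation_dataset(base_cfg, grid)


@pytest.fixture(scope="session")
def records(records_truth):
    return records_truth[0]


@pytest.fixture(scope="session")
def truth(records_truth):
    return records_truth[1]


@pytest.fixture(scope="session")
def econ(base_cfg):
    return generate_econ_tables(base_cfg)


@pytest.fixture(scope="session")
def fitted(records):
    """Full 256-model enumeration + selection on the base records."""
    return tt.ESValueModel(records).fit()


@pytest.fixture(scope="session")
def zero_noise_system():
    """A noise-free study system: log values equal the linear predictor."""
    cfg = tt.SynthConfig(grid_nx=10, grid_ny=10, n_countries=3, n_records=60,
                         sigma_country=0.0, sigma_resid=1e-8, rng_seed=5)
    g = generate_landscape(cfg)
    rec, tr = generate_valuation_dataset(cfg, g)
    return cfg, g, rec, tr
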