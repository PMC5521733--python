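"""Generator contracts: determinism, invariants, and known-truth moments."""

import numpy as np
import pytest
from scipy import stats

import tevtrade as tt
from tevtrade.config import CATTLE
from tevtrade.exceptions import ConfigurationError
from tevtrade.synthgen import (generate_econ_tables, generate_landscape,
                               generate_valuation_dataset)


def test_same_seed_bit_identical_outputs(base_cfg, grid, records, econ):
    g2 = generate_landscape(base_cfg)
    assert g2.data.identical(grid.data)
    assert g2.crop_composition.equals(grid.crop_composition)
    rec2, _ = generate_valuation_dataset(base_cfg, g2)
    assert rec2.equals(records)
    econ2 = generate_econ_tables(base_cfg)
    assert econ2.crop_prices.equals(econ.crop_prices)
    assert np.array_equal(econ2.scc_pool, econ.scc_pool)
    assert econ2.carbon_market.equals(econ.carbon_market)


def test_zero_loss_fraction_gives_no_loss():
    cfg = tt.SynthConfig(grid_nx=10, grid_ny=10, forest_loss_fraction=0.0,
                         n_countries=2, rng_seed=1)
    g = generate_landscape(cfg)
    assert np.all(g.layer("forest_loss_area") == 0.0)


def test_loss_cell_count_within_binomial_band():
    cfg = tt.SynthConfig(grid_nx=100, grid_ny=100, forest_loss_fraction=0.3,
                         n_countries=5, rng_seed=2)
    g = generate_landscape(cfg)
    count = int((g.layer("forest_loss_area") > 0).sum())
    sigma = np.sqrt(10_000 * 0.3 * 0.7)
    assert abs(count - 3000) <= 3 * sigma


def test_grid_invariants(grid, base_cfg):
    loss = grid.layer("forest_loss_area")
    assert loss.min() >= 0 and loss.max() <= base_cfg.cell_area
    assert set(np.unique(grid.layer("country_id"))) == set(range(4))
    # countries are contiguous blocks in row-major order
    flat = grid.flat("country_id")
    assert np.all(np.diff(flat) >= 0)
    for layer in ("agb_carbon", "bgb_carbon", "dom_carbon", "peat_depth"):
        assert grid.layer(layer).min() >= 0


def test_zero_noise_log_values_equal_linear_predictor(zero_noise_system):
    _, _, rec, tr = zero_noise_system
    assert np.allclose(rec["log_value"], tr.linear_predictor, atol=1e-6)


def test_records_read_covariates_from_their_grid_cell(records, grid):
    cells = records["cell_id"].to_numpy()
    assert np.array_equal(records["temperature"].to_numpy(),
                          grid.flat("temperature")[cells])
    assert np.array_equal(records["country"].to_numpy(),
                          grid.flat("country_id").astype(int)[cells])


def test_default_record_count_is_78(base_cfg, records):
    assert base_cfg.n_records == 78
    assert len(records) == 78


def test_country_effect_variance_within_chisquare_band():
    """Per-country mean residuals decompose the configured variance."""
    cfg = tt.SynthConfig(grid_nx=60, grid_ny=60, n_countries=20,
                         n_records=5000, rng_seed=3)
    g = generate_landscape(cfg)
    rec, tr = generate_valuation_dataset(cfg, g)
    resid = rec["log_value"].to_numpy() - tr.linear_predictor
    means = rec.groupby("country").apply(
        lambda s: resid[s.index].mean(), include_groups=False)
    counts = rec.groupby("country").size()
    # Var of a country mean: sigma1^2 + sigma^2 / n_c
    expected = cfg.sigma_country ** 2 + (cfg.sigma_resid ** 2 / counts).mean()
    G = len(means)
    stat = (G - 1) * means.var(ddof=1) / expected
    lo, hi = stats.chi2.ppf([0.005, 0.995], G - 1)
    assert lo <= stat <= hi


def test_generated_noise_moments_match_config():
    cfg = tt.SynthConfig(grid_nx=60, grid_ny=60, n_countries=20,
                         n_records=5000, rng_seed=4)
    g = generate_landscape(cfg)
    rec, tr = generate_valuation_dataset(cfg, g)
    a_c = rec["country"].map(tr.country_effects).to_numpy()
    eps = rec["log_value"].to_numpy() - tr.linear_predictor - a_c
    assert np.std(eps) == pytest.approx(cfg.sigma_resid, rel=0.05)
    effects = np.array(list(tr.country_effects.values()))
    assert effects.std(ddof=1) == pytest.approx(cfg.sigma_country, rel=0.5)


def test_price_cv_zero_gives_zero_sds():
    cfg = tt.SynthConfig(grid_nx=5, grid_ny=5, n_countries=2, price_cv=0.0,
                         rng_seed=1)
    econ = generate_econ_tables(cfg)
    assert np.all(econ.crop_prices["sd"].to_numpy() == 0.0)


def test_carbon_price_defaults_centre_on_reference_values(econ):
    assert econ.carbon_market["price"].mean() == pytest.approx(13.6, abs=1e-9)
    assert econ.scc_pool.mean() == pytest.approx(30.0, abs=1e-9)


def test_every_crop_country_combination_has_a_price(base_cfg, econ):
    crops = set(base_cfg.crop_set) | {CATTLE}
    got = set(map(tuple, econ.crop_prices[["crop", "country_id"]].to_numpy()))
    expected = {(c, k) for c in crops for k in range(base_cfg.n_countries)}
    assert got == expected
    assert (econ.crop_prices["mean"] >= 0).all()


def test_collinearity_knob_duplicates_covariate():
    cfg = tt.SynthConfig(grid_nx=10, grid_ny=10, n_countries=2,
                         collinear_covariate="temperature",
                         collinear_noise_sd=0.01, rng_seed=9)
    g = generate_landscape(cfg)
    dup = g.flat("temperature_dup")
    base = g.flat("temperature")
    assert np.corrcoef(dup, base)[0, 1] > 0.999
    rec, _ = generate_valuation_dataset(cfg, g)
    assert "temperature_dup" in rec.columns


@pytest.mark.parametrize("field, value", [
    ("grid_nx", 0),
    ("forest_loss_fraction", 1.5),
    ("sigma_resid", -1.0),
    ("n_countries", 1000),
    ("n_records", 0),
])
def test_invalid_config_raises_naming_the_field(field, value):
    kwargs = {"grid_nx": 5, "grid_ny": 5}
    kwargs[field] = value
    with pytest.raises(ConfigurationError):
        tt.SynthConfig(**kwargs)


def test_fewer_records_than_countries_warns():
    cfg = tt.SynthConfig(grid_nx=10, grid_ny=10, n_countries=8, n_records=4,
                         rng_seed=2)
    g = generate_landscape(cfg)
    with pytest.warns(UserWarning, match="fixed effects only"):
        generate_valuation_dataset(cfg, g)
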