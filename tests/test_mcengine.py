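"""Monte Carlo propagation: perturbation, price sampling, reduction."""

import numpy as np
import pandas as pd
import pytest

import tevtrade as tt
from tevtrade._rng import stream
from tevtrade.config import UncertaintySpec
from tevtrade.mcengine import (MonteCarloEngine, OutcomeEnsemble, PriceDraw,
                               perturb_loss_map, reduce_percentiles,
                               sample_prices)
from tevtrade.synthgen import (generate_econ_tables, generate_landscape,
                               generate_valuation_dataset)

ALL_OFF = {"carbon_market": False, "carbon_social": False,
           "crop_prices": False, "es_bootstrap": False,
           "crop_assignment": False}


# -- loss-map perturbation -------------------------------------------------

def test_perfect_accuracies_leave_map_unchanged(grid):
    spec = UncertaintySpec(loss_accuracy=1.0, noloss_accuracy=1.0)
    out = perturb_loss_map(grid.layer("forest_loss_area"), spec, stream(0, "x"))
    assert np.array_equal(out, grid.layer("forest_loss_area"))


def test_zero_loss_accuracy_removes_all_loss(grid):
    spec = UncertaintySpec(loss_accuracy=0.0, noloss_accuracy=1.0)
    out = perturb_loss_map(grid.layer("forest_loss_area"), spec, stream(0, "x"))
    assert np.all(out == 0.0)


def test_loss_retention_within_binomial_band():
    cfg = tt.SynthConfig(grid_nx=120, grid_ny=120, forest_loss_fraction=0.7,
                         n_countries=3, rng_seed=2)
    g = generate_landscape(cfg)
    loss = g.layer("forest_loss_area")
    n_loss = int((loss > 0).sum())
    spec = UncertaintySpec(loss_accuracy=0.87, noloss_accuracy=1.0)
    out = perturb_loss_map(loss, spec, stream(3, "loss"))
    retained = int(((out > 0) & (loss > 0)).sum())
    sigma = np.sqrt(n_loss * 0.87 * 0.13)
    assert abs(retained - 0.87 * n_loss) <= 3 * sigma


def test_flipped_cells_receive_country_mean_loss_area(grid):
    spec = UncertaintySpec(loss_accuracy=1.0, noloss_accuracy=0.5)
    loss = grid.layer("forest_loss_area")
    country = grid.layer("country_id").astype(int)
    out = perturb_loss_map(loss, spec, stream(1, "loss"), country_id=country)
    flipped = (loss == 0) & (out > 0)
    assert flipped.any()
    for c in np.unique(country):
        mean_c = loss[(country == c) & (loss > 0)].mean()
        sel = flipped & (country == c)
        if sel.any():
            assert np.allclose(out[sel], mean_c)


# -- price sampling --------------------------------------------------------

def test_inactive_sources_collapse_to_central_values(econ):
    spec = UncertaintySpec(sources=dict(ALL_OFF), seed=0)
    draw = sample_prices(econ, spec)
    assert draw.carbon_market == pytest.approx(13.6, abs=1e-9)
    assert draw.carbon_social == pytest.approx(30.0, abs=1e-9)
    assert draw.crop is None


def test_singleton_series_always_sampled(econ):
    econ2 = tt.EconTables(
        crop_prices=econ.crop_prices, crop_params=econ.crop_params,
        country_params=econ.country_params,
        carbon_market=pd.DataFrame({"date": ["2012-01-01"], "price": [9.9]}),
        scc_pool=econ.scc_pool, internalization=econ.internalization)
    spec = UncertaintySpec(seed=1)
    for rep in range(5):
        assert sample_prices(econ2, spec, rep=rep).carbon_market == 9.9


def test_zero_sd_crop_price_equals_mean():
    cfg = tt.SynthConfig(grid_nx=3, grid_ny=3, n_countries=1, price_cv=0.0,
                         crop_set=("maize",), rng_seed=4)
    econ = generate_econ_tables(cfg)
    draw = sample_prices(econ, UncertaintySpec(seed=2))
    assert draw.crop[("maize", 0)] == econ.price("maize", 0)[0]


def test_sampled_price_mean_within_clt_band():
    cfg = tt.SynthConfig(grid_nx=3, grid_ny=3, n_countries=1,
                         crop_set=("maize",), rng_seed=5)
    econ = generate_econ_tables(cfg)
    mean, sd = econ.price("maize", 0)
    spec = UncertaintySpec(seed=6)
    draws = np.array([sample_prices(econ, spec, rep=r).crop[("maize", 0)]
                      for r in range(2000)])
    assert abs(draws.mean() - mean) <= 3 * sd / np.sqrt(2000)
    assert draws.std() == pytest.approx(sd, rel=0.1)


def test_stream_splitting_isolates_sources(econ):
    """Toggling one source must not change another source's draws."""
    on = UncertaintySpec(seed=7)
    off = UncertaintySpec(seed=7, sources={"carbon_market": False})
    for rep in (0, 3):
        assert (sample_prices(econ, on, rep).crop
                == sample_prices(econ, off, rep).crop)
        assert (sample_prices(econ, on, rep).carbon_social
                == sample_prices(econ, off, rep).carbon_social)


# -- the engine ------------------------------------------------------------

@pytest.fixture(scope="module")
def mc_system(records, grid, econ, fitted):
    ensemble = fitted.bootstrap_maps(grid, B=10, seed=1)
    return grid, ensemble, econ


def test_degenerate_spec_collapses_to_point_estimate(mc_system):
    grid, ensemble, econ = mc_system
    spec = UncertaintySpec(n_reps=6, loss_accuracy=1.0, noloss_accuracy=1.0,
                           sources=dict(ALL_OFF), seed=3)
    out = MonteCarloEngine(grid, ensemble, econ, "C", spec).run()
    for m in range(1, out.M):
        assert np.array_equal(out.impact_maps[m], out.impact_maps[0])
    pct = out.percentile_maps()
    assert np.array_equal(pct[2.5], pct[97.5])
    # ensemble variance collapses to zero exactly
    assert out.aggregates["impact_total"].var() == 0.0


def test_seed_reproducibility_of_full_ensemble(mc_system):
    grid, ensemble, econ = mc_system
    spec = UncertaintySpec(n_reps=5, seed=11)
    out1 = MonteCarloEngine(grid, ensemble, econ, "A", spec).run()
    out2 = MonteCarloEngine(grid, ensemble, econ, "A", spec).run()
    assert np.array_equal(out1.impact_maps, out2.impact_maps)
    assert out1.aggregates.equals(out2.aggregates)


def test_percentile_monotonicity(mc_system):
    grid, ensemble, econ = mc_system
    spec = UncertaintySpec(n_reps=20, seed=12)
    out = MonteCarloEngine(grid, ensemble, econ, "A", spec).run()
    pct = out.percentile_maps()
    assert np.all(pct[2.5] <= pct[50.0] + 1e-12)
    assert np.all(pct[50.0] <= pct[97.5] + 1e-12)
    table = out.percentile_table()
    assert (table["p2.5"] <= table["p97.5"] + 1e-9).all()


def test_adding_a_source_does_not_decrease_variance(mc_system):
    grid, ensemble, econ = mc_system
    vars_one, vars_two = [], []
    for seed in range(20):
        base = dict(ALL_OFF, crop_prices=True)
        spec1 = UncertaintySpec(n_reps=30, loss_accuracy=1.0,
                                noloss_accuracy=1.0, sources=base, seed=seed)
        spec2 = UncertaintySpec(n_reps=30, loss_accuracy=1.0,
                                noloss_accuracy=1.0,
                                sources=dict(base, carbon_market=True),
                                seed=seed)
        out1 = MonteCarloEngine(grid, ensemble, econ, "C", spec1).run()
        out2 = MonteCarloEngine(grid, ensemble, econ, "C", spec2).run()
        vars_one.append(out1.aggregates["impact_total"].var())
        vars_two.append(out2.aggregates["impact_total"].var())
    assert np.mean(vars_two) >= np.mean(vars_one)


def test_uniform_ensemble_quantiles_match_analytic():
    rng = np.random.default_rng(13)
    draws = rng.uniform(0.0, 1.0, 10_000)
    ens = OutcomeEnsemble(
        impact_maps=draws.reshape(-1, 1, 1),
        aggregates=pd.DataFrame({"impact_total": draws}),
        country_aggregates=pd.DataFrame(),
        spec=UncertaintySpec(n_reps=10_000), scenario_id="A")
    red = reduce_percentiles(ens)
    assert red["maps"][2.5][0, 0] == pytest.approx(0.025, abs=0.01)
    assert red["maps"][50.0][0, 0] == pytest.approx(0.5, abs=0.02)


def test_one_cell_variance_matches_closed_form_propagation():
    """With only crop-price uncertainty, Var[impact] = (y A)^2 sd_p^2."""
    cfg = tt.SynthConfig(grid_nx=1, grid_ny=1, n_countries=1, n_records=10,
                         crop_set=("maize",), forest_loss_fraction=1.0,
                         rng_seed=8)
    g = generate_landscape(cfg)
    g.crop_composition.loc[0] = [1.0, 0.0]  # maize only
    rec, _ = generate_valuation_dataset(cfg, g)
    econ = generate_econ_tables(cfg)
    res = tt.ESValueModel(rec, candidate_terms=("temperature",)).fit()
    ens = res.bootstrap_maps(g, B=1, seed=0, force_full_sample=True)
    spec = UncertaintySpec(n_reps=2000, loss_accuracy=1.0, noloss_accuracy=1.0,
                           sources=dict(ALL_OFF, crop_prices=True), seed=11)
    out = MonteCarloEngine(g, ens, econ, "A", spec).run()
    y = g.flat("yield_maize")[0]
    area = g.flat("forest_loss_area")[0]
    sd_p = econ.price("maize", 0)[1]
    analytic = (y * area * sd_p) ** 2
    empirical = out.aggregates["impact_total"].var(ddof=1)
    assert empirical == pytest.approx(analytic, rel=0.15)  # ~4 MC sigma
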