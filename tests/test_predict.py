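"""Model-averaged prediction and the per-cell TEV aggregation."""

import numpy as np
import pandas as pd
import pytest

import tevtrade as tt
from tevtrade.esmeta import average_predict, predict_single, predict_tev_grid
from tevtrade.exceptions import ConfigurationError
from tevtrade.synthgen import generate_landscape, generate_valuation_dataset, grid_newdata

from conftest import TRUE_TERMS


def test_averaging_is_weighted_sum_of_component_predictions(fitted, grid):
    nd = grid_newdata(grid).head(50).assign(es_class="cultural",
                                            method_class="stated")
    per_model = np.stack([predict_single(m, fitted.model_set, nd)
                          for m in fitted.top_models])
    expected = fitted.top_weights @ per_model
    got = average_predict(fitted.model_set, nd)
    assert np.allclose(got, expected, atol=1e-12)
    # convex combination: averaged prediction within component bounds
    assert np.all(got <= per_model.max(axis=0) + 1e-12)
    assert np.all(got >= per_model.min(axis=0) - 1e-12)


def test_single_model_averaging_is_identity(zero_noise_system):
    _, _, rec, _ = zero_noise_system
    res = tt.ESValueModel(rec, candidate_terms=TRUE_TERMS).fit()
    assert res.n_top == 1
    nd = rec.head(10)
    assert np.allclose(res.predict(nd),
                       predict_single(res.top_models[0], res.model_set, nd))


def test_absent_year_fixed_at_training_mean(fitted, grid):
    nd = grid_newdata(grid).head(20).assign(es_class="cultural",
                                            method_class="stated")
    pred_absent = average_predict(fitted.model_set, nd)
    year_mean = fitted.model_set.builder.means.get("year")
    assert year_mean is not None
    pred_mean = average_predict(fitted.model_set, nd.assign(year=year_mean))
    assert np.allclose(pred_absent, pred_mean, atol=1e-10)


def test_unseen_country_predicted_with_fixed_effects_only(fitted, grid):
    nd = grid_newdata(grid).head(5).assign(es_class="cultural",
                                           method_class="stated",
                                           country=9999)
    conditional = average_predict(fitted.model_set, nd, mode="conditional")
    fixed_only = average_predict(fitted.model_set, nd, mode="fixed")
    assert np.allclose(conditional, fixed_only)


def test_missing_covariate_error_names_it(fitted, grid):
    nd = grid_newdata(grid).head(5).assign(es_class="cultural",
                                           method_class="stated")
    nd = nd.drop(columns=["temperature"])
    with pytest.raises(KeyError, match="temperature"):
        average_predict(fitted.model_set, nd)


def _constant_value_system(values=(30.0, 10.0, 20.0)):
    """Zero-noise system whose ES-class values are exactly (cult, prov, reg)."""
    cult, prov, reg = values
    beta = {"intercept": float(np.log(cult)),
            "es_class[provisioning]": float(np.log(prov / cult)),
            "es_class[regulating]": float(np.log(reg / cult))}
    cfg = tt.SynthConfig(grid_nx=5, grid_ny=5, n_countries=1, n_records=30,
                         sigma_country=0.0, sigma_resid=1e-9,
                         true_beta=beta, rng_seed=11)
    g = generate_landscape(cfg)
    rec, _ = generate_valuation_dataset(cfg, g)
    res = tt.ESValueModel(rec, candidate_terms=("es_class",)).fit()
    return g, res


def test_tev_multiplier_hand_arithmetic():
    """Class values (prov, reg, cult) = (10, 20, 30) with multipliers
    (5, 6, 5) give TEV = 50 + 120 + 150 = 320 per hectare."""
    g, res = _constant_value_system()
    tev, comps = res.predict_tev(g)
    assert np.allclose(comps["provisioning"], 10.0, rtol=1e-5)
    assert np.allclose(comps["regulating"], 20.0, rtol=1e-5)
    assert np.allclose(comps["cultural"], 30.0, rtol=1e-5)
    assert np.allclose(tev, 320.0, rtol=1e-5)


def test_zero_multipliers_give_zero_tev(fitted, grid):
    tev, _ = predict_tev_grid(fitted.model_set, grid,
                              multipliers={"provisioning": 0.0,
                                           "regulating": 0.0,
                                           "cultural": 0.0})
    assert np.all(tev == 0.0)


def test_negative_multiplier_is_config_error(fitted, grid):
    with pytest.raises(ConfigurationError):
        predict_tev_grid(fitted.model_set, grid,
                         multipliers={"provisioning": -1.0})


def test_uniform_covariates_give_constant_tev_map():
    g, res = _constant_value_system()
    # covariates vary across cells but the model uses only es_class,
    # and there is a single country: the TEV surface must be constant
    tev, _ = res.predict_tev(g)
    assert np.ptp(tev) < 1e-8


def test_tev_invariant_to_record_and_cell_order(records, grid, fitted):
    tev, _ = predict_tev_grid(fitted.model_set, grid)
    # record order: refit on shuffled records
    shuffled = records.sample(frac=1.0, random_state=1).reset_index(drop=True)
    res2 = tt.ESValueModel(shuffled).fit()
    tev2, _ = predict_tev_grid(res2.model_set, grid)
    # order-invariant up to optimizer/summation tolerance
    assert np.allclose(tev, tev2, rtol=1e-6)
    # cell order: swapping grid rows swaps prediction rows
    swapped = grid.data.isel(y=list(reversed(range(grid.ny))))
    g2 = tt.LandscapeGrid(swapped, grid.cell_area, grid.crops,
                          grid.crop_composition, grid.country_region)
    tev3, _ = predict_tev_grid(fitted.model_set, g2)
    assert np.allclose(tev3, tev[::-1, :], rtol=1e-12)


def test_averaged_coefficient_table(fitted):
    params = fitted.params
    assert "intercept" in params.index
    assert (params["importance"] <= 1.0 + 1e-12).all()
    assert (params["se"] > 0).all()
    assert fitted.summary().startswith("ES-value meta-analytic")
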