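"""Agricultural rents: components, scenarios, and a scalar brute-force oracle."""

import numpy as np
import pytest

import tevtrade as tt
from tevtrade.agrorent import (candidate_crops, cattle_rent, net_rent,
                               production_costs, rent_map, timber_rent,
                               transport_cost, assign_crops, _rent_components)
from tevtrade.config import CATTLE, ScenarioSpec, TruckParams
from tevtrade.econ import EconTables
from tevtrade.exceptions import ConfigurationError
from tevtrade.synthgen import generate_econ_tables, generate_landscape

A, B, C, D = (ScenarioSpec.from_id(s) for s in "ABCD")


def test_transport_cost_hand_arithmetic():
    truck = TruckParams(capacity_m3=18, speed_kmh=45, fuel_l_per_km=0.3,
                        density_t_per_m3=1.0)
    # 2h one-way: 180 km round trip -> 54 fuel + 20 wages = 74 per 18 t load
    out = transport_cost(2.0, wage_hour=5.0, fuel_price=1.0, truck=truck)
    assert out == pytest.approx(74.0 / 18.0, abs=0.01)


def test_transport_zero_travel_time_is_free():
    assert transport_cost(0.0, 5.0, 1.0) == 0.0


def test_truck_defaults_match_reference_assumptions():
    truck = TruckParams()
    assert truck.capacity_m3 == 18.0
    assert truck.speed_kmh == 45.0


def test_zero_capacity_truck_rejected():
    with pytest.raises(ConfigurationError):
        TruckParams(capacity_m3=0.0)


@pytest.fixture()
def small_econ():
    cfg = tt.SynthConfig(grid_nx=5, grid_ny=5, n_countries=2, rng_seed=20)
    econ = generate_econ_tables(cfg)
    econ.crop_params.loc["maize", "persondays"] = 100.0
    econ.country_params.loc[0, "wage_agri_day"] = 2.0
    return econ


def test_labor_cost_hand_arithmetic(small_econ):
    cc = production_costs("maize", 0, small_econ, A, yield_t=2.0,
                          travel_time=3.0, fertilizer_usage=0.0)
    assert cc.labor == pytest.approx(200.0)
    assert cc.transport == 0.0  # national-sample scenarios exclude transport
    assert cc.total == pytest.approx(200.0)


def test_gross_scenarios_have_zero_costs(small_econ):
    cc = production_costs("maize", 0, small_econ, B, yield_t=2.0,
                          travel_time=3.0, fertilizer_usage=50.0)
    assert cc.total == 0.0


def test_max_rent_scenario_adds_transport(small_econ):
    cc_a = production_costs("maize", 0, small_econ, A, yield_t=2.0,
                            travel_time=3.0, fertilizer_usage=50.0)
    cc_c = production_costs("maize", 0, small_econ, C, yield_t=2.0,
                            travel_time=3.0, fertilizer_usage=50.0)
    assert cc_c.transport > 0
    assert cc_c.total >= cc_a.total


def test_wage_fallback_chain(small_econ):
    small_econ.country_params.loc[0, "wage_agri_day"] = np.nan
    assert small_econ.wage_day(0) == small_econ.country_params.loc[
        0, "wage_manuf_day"]
    small_econ.country_params.loc[0, "wage_manuf_day"] = np.nan
    with pytest.raises(ConfigurationError):
        small_econ.wage_day(0)


def test_missing_price_falls_back_to_donor_then_zero(small_econ):
    keep = ~((small_econ.crop_prices["crop"] == "maize")
             & (small_econ.crop_prices["country_id"] == 0))
    econ2 = EconTables(
        crop_prices=small_econ.crop_prices[keep].reset_index(drop=True),
        crop_params=small_econ.crop_params,
        country_params=small_econ.country_params,
        carbon_market=small_econ.carbon_market,
        scc_pool=small_econ.scc_pool,
        internalization=small_econ.internalization,
        price_fallback_country={0: 1},
    )
    assert econ2.price("maize", 0) == econ2.price("maize", 1)
    econ3 = EconTables(
        crop_prices=small_econ.crop_prices[keep].reset_index(drop=True),
        crop_params=small_econ.crop_params,
        country_params=small_econ.country_params,
        carbon_market=small_econ.carbon_market,
        scc_pool=small_econ.scc_pool,
        internalization=small_econ.internalization,
        price_fallback_country={},
    )
    with pytest.warns(UserWarning, match="maize"):
        assert econ3.price("maize", 0) == (0.0, 0.0)


def test_net_rent_identity_and_sign():
    assert net_rent(2.0, 300.0, 100.0) == pytest.approx(500.0)
    assert net_rent(2.0, 300.0, 0.0) == pytest.approx(600.0)
    assert net_rent(1.0, 50.0, 100.0) == pytest.approx(-50.0)  # not clipped


def test_timber_rent_hand_arithmetic():
    assert timber_rent(200.0, 0.3, 50.0, r=0.05, T=100.0) == pytest.approx(
        151.15, abs=0.05)
    assert timber_rent(200.0, 0.0, 50.0) == 0.0
    assert timber_rent(200.0, 0.3, 50.0, r=0.0, T=100.0) == pytest.approx(30.0)


def test_cattle_rent_hand_arithmetic():
    assert cattle_rent(1.0, 0.25, 2000.0, 100.0) == pytest.approx(400.0)
    assert cattle_rent(0.0, 0.25, 2000.0, 100.0) == pytest.approx(-100.0)
    assert cattle_rent(2.0, 0.25, 2000.0, 0.0) == pytest.approx(
        2 * cattle_rent(1.0, 0.25, 2000.0, 0.0))


def _single_country_grid(crop_set=("maize", "rice"), weights=(0.7, 0.3, 0.0),
                         nx=100, ny=100, seed=21):
    cfg = tt.SynthConfig(grid_nx=nx, grid_ny=ny, n_countries=1,
                         crop_set=crop_set, forest_loss_fraction=1.0,
                         rng_seed=seed)
    g = generate_landscape(cfg)
    g.crop_composition.loc[0] = list(weights)
    return cfg, g


def test_one_crop_country_gets_that_crop_everywhere():
    cfg, g = _single_country_grid(weights=(1.0, 0.0, 0.0), nx=10, ny=10)
    econ = generate_econ_tables(cfg)
    assignment = assign_crops(g, A, econ, rng=1)
    loss = g.flat("forest_loss_area") > 0
    assert np.all(assignment.ravel()[loss] == 0)  # maize index


def test_national_sampling_frequencies_within_binomial_band():
    cfg, g = _single_country_grid()
    econ = generate_econ_tables(cfg)
    assignment = assign_crops(g, A, econ, rng=2).ravel()
    loss = g.flat("forest_loss_area") > 0
    n = int(loss.sum())
    maize = int((assignment[loss] == 0).sum())
    sigma = np.sqrt(n * 0.7 * 0.3)
    assert abs(maize - 0.7 * n) <= 3 * sigma


def test_assignment_seeded_reproducibility(grid, econ):
    a1 = assign_crops(grid, A, econ, rng=5)
    a2 = assign_crops(grid, A, econ, rng=5)
    assert np.array_equal(a1, a2)


def test_argmax_assignment_is_optimal(grid, econ):
    assignment = assign_crops(grid, C, econ).ravel()
    _, gross, costs = _rent_components(grid, C, econ, None)
    rent = gross - costs
    loss = grid.flat("forest_loss_area") > 0
    idx = np.flatnonzero(loss)
    best = rent[:, idx].max(axis=0)
    chosen = rent[assignment[idx], idx]
    assert np.allclose(chosen, best, atol=1e-9)


def _brute_force_rent(grid, scenario, econ, assignment):
    """Per-cell scalar recomputation from the component functions."""
    crops = candidate_crops(grid)
    out = np.zeros(grid.n_cells)
    loss = grid.flat("forest_loss_area")
    country = grid.flat("country_id").astype(int)
    for i in range(grid.n_cells):
        if loss[i] <= 0:
            continue
        c = int(country[i])
        crop = crops[assignment.ravel()[i]]
        if crop == CATTLE:
            costs = (econ.persondays(CATTLE) * econ.wage_day(c)
                     if scenario.deduct_costs else 0.0)
            rent = cattle_rent(grid.flat("cattle_stocking")[i],
                               econ.country_value(c, "carcass_efficiency"),
                               econ.price(CATTLE, c)[0], costs)
        else:
            prefix = ("potential_yield_" if scenario.uses_potential_yield
                      else "yield_")
            y = grid.flat(prefix + crop)[i]
            cc = production_costs(crop, c, econ, scenario, y,
                                  grid.flat("travel_time")[i],
                                  grid.flat("fertilizer_usage")[i])
            rent = net_rent(y, econ.price(crop, c)[0], cc.total)
        rent += timber_rent(grid.flat("growing_stock")[i],
                            econ.country_value(c, "commercial_fraction"),
                            econ.country_value(c, "timber_export_price"))
        out[i] = rent
    return out.reshape(grid.shape)


@pytest.mark.parametrize("scenario", [A, B, C, D], ids="ABCD")
def test_rent_map_matches_scalar_brute_force(grid, econ, scenario):
    ar, assignment = rent_map(grid, scenario, econ, rng=9)
    expected = _brute_force_rent(grid, scenario, econ, assignment)
    assert np.max(np.abs(ar - expected)) < 1e-9


def test_scenario_dominance_under_shared_seed(grid, econ):
    ar_a, assign_a = rent_map(grid, A, econ, rng=4)
    ar_b, assign_b = rent_map(grid, B, econ, rng=4)
    assert np.array_equal(assign_a, assign_b)
    assert np.all(ar_b >= ar_a - 1e-12)
    ar_c, _ = rent_map(grid, C, econ)
    ar_d, _ = rent_map(grid, D, econ)
    assert np.all(ar_d >= ar_c - 1e-12)


def test_potential_rents_exceed_current_rents_in_expectation(econ, base_cfg):
    diffs = []
    for seed in range(5):
        g = generate_landscape(tt.SynthConfig(
            grid_nx=15, grid_ny=15, n_countries=4, rng_seed=100 + seed))
        ar_a, _ = rent_map(g, A, econ, rng=seed)
        ar_c, _ = rent_map(g, C, econ)
        loss = g.layer("forest_loss_area") > 0
        diffs.append(ar_c[loss].mean() - ar_a[loss].mean())
    assert np.mean(diffs) > 0


def test_no_deforestation_gives_zero_rent_map(econ):
    cfg = tt.SynthConfig(grid_nx=8, grid_ny=8, n_countries=2,
                         forest_loss_fraction=0.0, rng_seed=2)
    g = generate_landscape(cfg)
    ar, assignment = rent_map(g, C, econ)
    assert np.all(ar == 0.0)
    assert np.all(assignment == -1)
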