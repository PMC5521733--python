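"""Seeded synthetic landscapes, valuation datasets, and economic tables.

The generator emulates the three inputs of the trade-off analysis with a
fully known ground truth:

* a gridded tropical landscape (forest loss, carbon pools, peat, yields,
  socio-environmental covariates, country blocks),
* a valuation-study table drawn from a log-linear model with a country
  random intercept — ``log(value) = a + sum_j b_j X_j + a_c + e`` with
  ``a_c ~ N(0, s1^2)`` and ``e ~ N(0, s^2)`` — whose true coefficients and
  realized country effects are returned alongside for test oracles,
* economic tables (crop prices with uncertainty, wages, fuel, timber,
  cattle, the market carbon-price series and the social-cost draw pool).

Everything is deterministic given ``SynthConfig.rng_seed``; independent
named substreams keep the three generators decoupled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from ._rng import stream
from .config import CATTLE, SynthConfig
from .design import (ES_LEVELS, METHOD_LEVELS, DesignMatrixBuilder,
                     beta_vector, terms_from_beta)
from .econ import INTERNALIZATION_CATEGORIES, EconTables
from .grid import LandscapeGrid

# Reference farm-gate prices (currency/t) and yields (t/ha/yr) for the 18
# major tropical crops; country-level tables are drawn around these.
BASE_PRICE = {
    "banana": 300.0, "bean": 600.0, "cassava": 100.0, "cocoa": 2500.0,
    "coconut": 200.0, "coffee": 2000.0, "cotton": 1500.0, "cowpea": 500.0,
    "groundnut": 800.0, "maize": 150.0, "millet": 300.0, "oil_palm": 150.0,
    "rice": 250.0, "rubber": 1500.0, "sorghum": 200.0, "soybean": 350.0,
    "sugar_cane": 30.0, "wheat": 200.0, CATTLE: 2500.0,
}
BASE_YIELD = {
    "banana": 20.0, "bean": 1.0, "cassava": 12.0, "cocoa": 0.6,
    "coconut": 6.0, "coffee": 1.0, "cotton": 2.0, "cowpea": 1.0,
    "groundnut": 1.5, "maize": 4.0, "millet": 1.0, "oil_palm": 18.0,
    "rice": 4.0, "rubber": 1.2, "sorghum": 1.5, "soybean": 2.5,
    "sugar_cane": 65.0, "wheat": 3.0,
}
BASE_PERSONDAYS = {
    "banana": 100.0, "bean": 60.0, "cassava": 80.0, "cocoa": 120.0,
    "coconut": 50.0, "coffee": 150.0, "cotton": 120.0, "cowpea": 50.0,
    "groundnut": 80.0, "maize": 60.0, "millet": 50.0, "oil_palm": 90.0,
    "rice": 150.0, "rubber": 150.0, "sorghum": 50.0, "soybean": 30.0,
    "sugar_cane": 120.0, "wheat": 40.0, CATTLE: 10.0,
}

#: uniform covariate ranges used for both grid cells and (via cells) records
COVARIATE_RANGES = {
    "temperature": (20.0, 30.0),        # deg C
    "precipitation": (1000.0, 3500.0),  # mm/yr
    "accessibility": (0.5, 24.0),       # h to nearest city
    "population": (1.0, 300.0),         # inhabitants/km^2
    "altitude": (0.0, 2000.0),          # m
    "gdp": (500.0, 20000.0),            # per-capita, currency
    "richness_birds": (100.0, 600.0),
    "richness_amphibians": (10.0, 150.0),
    "richness_mammals": (10.0, 200.0),
    "richness_plants": (500.0, 5000.0),
    "carbon_density": (50.0, 250.0),    # tC/ha
}

REGION_NAMES = ("americas", "africa", "asia")


@dataclass
class SynthTruth:
    """Ground truth of a generated valuation dataset (test oracle)."""

    beta: dict[str, float]
    sigma_country: float
    sigma_resid: float
    country_effects: dict[int, float]
    linear_predictor: np.ndarray
    builder: DesignMatrixBuilder


def generate_landscape(config: SynthConfig) -> LandscapeGrid:
    """Generate a seeded synthetic landscape grid."""
    rng = stream(config.rng_seed, "landscape")
    ny, nx = config.grid_ny, config.grid_nx
    n = ny * nx

    def uniform(lo, hi):
        return rng.uniform(lo, hi, size=(ny, nx))

    # countries: contiguous row-major blocks (axis-aligned strips)
    country = ((np.arange(n) * config.n_countries) // n).reshape(ny, nx)

    data: dict[str, tuple[tuple[str, str], np.ndarray]] = {}
    data["country_id"] = (("y", "x"), country.astype(float))

    for name, (lo, hi) in COVARIATE_RANGES.items():
        data[name] = (("y", "x"), uniform(lo, hi))
    data["protected_area"] = (("y", "x"),
                              (rng.random((ny, nx)) < 0.3).astype(float))
    if config.collinear_covariate is not None:
        base = data[config.collinear_covariate][1]
        noise = rng.normal(0.0, config.collinear_noise_sd * np.std(base), (ny, nx))
        data[config.collinear_covariate + "_dup"] = (("y", "x"), base + noise)

    loss_mask = rng.random((ny, nx)) < config.forest_loss_fraction
    data["forest_loss_area"] = (
        ("y", "x"), loss_mask * rng.beta(2.0, 5.0, (ny, nx)) * config.cell_area)

    agb = uniform(80.0, 200.0)
    data["agb_carbon"] = (("y", "x"), agb)
    data["bgb_carbon"] = (("y", "x"), agb * uniform(0.15, 0.25))
    data["dom_carbon"] = (("y", "x"), uniform(2.0, 8.0))
    peat_mask = rng.random((ny, nx)) < config.peat_fraction
    depth = np.minimum(rng.exponential(config.peat_depth_mean, (ny, nx)),
                       config.peat_depth_max)
    data["peat_depth"] = (("y", "x"), peat_mask * depth)

    for crop in config.crop_set:
        base = BASE_YIELD.get(crop, 2.0)
        current = base * uniform(0.4, 1.0)
        data[f"yield_{crop}"] = (("y", "x"), current)
        data[f"potential_yield_{crop}"] = (("y", "x"), current * uniform(1.2, 2.5))

    data["pasture_fraction"] = (("y", "x"), rng.beta(1.5, 4.0, (ny, nx)))
    data["cattle_stocking"] = (("y", "x"), uniform(0.3, 2.0))   # head/ha
    data["travel_time"] = (("y", "x"), uniform(0.5, 12.0))      # h one-way
    data["fertilizer_usage"] = (("y", "x"), uniform(0.0, 200.0))  # kg/ha/yr
    data["growing_stock"] = (("y", "x"), uniform(50.0, 300.0))  # m^3/ha

    # per-country crop composition (area weights, cattle included)
    comp = rng.dirichlet(np.ones(len(config.crop_set) + 1),
                         size=config.n_countries)
    composition = pd.DataFrame(
        comp, columns=list(config.crop_set) + [CATTLE],
        index=pd.Index(range(config.n_countries), name="country_id"))

    regions = {c: REGION_NAMES[c % len(REGION_NAMES)]
               for c in range(config.n_countries)}
    return LandscapeGrid(xr.Dataset(data), cell_area=config.cell_area,
                         crops=config.crop_set, crop_composition=composition,
                         country_region=regions)


def generate_valuation_dataset(
        config: SynthConfig, grid: LandscapeGrid,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Draw a valuation-record table from the known log-linear model.

    Returns the record table and the generative truth (true coefficients,
    realized country effects, per-record linear predictor).
    """
    rng = stream(config.rng_seed, "valuation")
    n = config.n_records
    countries = grid.countries
    if n < len(countries):
        warnings.warn(
            f"{n} records over {len(countries)} countries: some countries have "
            "no records and will be predicted with fixed effects only",
            stacklevel=2)

    cells = rng.integers(0, grid.n_cells, size=n)
    records = pd.DataFrame({
        "study_id": rng.integers(0, config.n_studies, size=n),
        "es_class": rng.choice(ES_LEVELS, size=n),
        "method_class": rng.choice(METHOD_LEVELS, size=n),
        "peer_reviewed": (rng.random(n) < 0.7).astype(float),
        "year": rng.integers(1995, 2016, size=n).astype(float),
        "forest_area": np.exp(rng.normal(7.0, 1.5, size=n)),
        "cell_id": cells,
    })
    records["country"] = grid.flat("country_id").astype(int)[cells]
    records["region"] = records["country"].map(grid.country_region)
    for cov in list(COVARIATE_RANGES) + ["protected_area"]:
        records[cov] = grid.flat(cov)[cells]
    if config.collinear_covariate is not None:
        dup = config.collinear_covariate + "_dup"
        records[dup] = grid.flat(dup)[cells]

    terms = terms_from_beta(config.true_beta)
    builder = DesignMatrixBuilder(terms).fit(records)
    X, cols = builder.transform(records)
    eta = X @ beta_vector(config.true_beta, cols)

    effects = {int(c): rng.normal(0.0, config.sigma_country) for c in countries}
    a_c = records["country"].map(effects).to_numpy()
    eps = rng.normal(0.0, config.sigma_resid, size=n)
    records["log_value"] = eta + a_c + eps
    records["value"] = np.exp(records["log_value"])

    # screening flags: all clean by default (ablate deliberately in tests)
    records["benefit_transfer"] = False
    records["has_location"] = True
    records["has_es_type"] = True
    records["has_method"] = True
    records["is_npv"] = False
    records["discount_rate"] = np.nan
    records["horizon"] = np.nan

    truth = SynthTruth(
        beta=dict(config.true_beta),
        sigma_country=config.sigma_country,
        sigma_resid=config.sigma_resid,
        country_effects=effects,
        linear_predictor=eta,
        builder=builder,
    )
    return records, truth


def generate_econ_tables(config: SynthConfig) -> EconTables:
    """Generate seeded economic parameter tables.

    The market carbon-price series is centred on 13.6 currency/t and the
    social-cost pool on a mean of 30 currency/t (both rescaled to those
    means exactly, so the degenerate no-uncertainty run reproduces the
    reference prices).
    """
    rng = stream(config.rng_seed, "econ")
    countries = np.arange(config.n_countries)
    all_crops = list(config.crop_set) + [CATTLE]

    rows = []
    for crop in all_crops:
        base = BASE_PRICE.get(crop, 500.0)
        for c in countries:
            mean = base * rng.uniform(0.8, 1.2)
            rows.append((crop, int(c), mean, mean * config.price_cv))
    crop_prices = pd.DataFrame(rows, columns=["crop", "country_id", "mean", "sd"])

    crop_params = pd.DataFrame({
        "persondays": [BASE_PERSONDAYS.get(c, 80.0) for c in all_crops],
        "is_transported": [c != CATTLE for c in all_crops],
    }, index=pd.Index(all_crops, name="crop"))

    country_params = pd.DataFrame({
        "wage_agri_day": rng.uniform(2.0, 10.0, len(countries)),
        "wage_manuf_day": rng.uniform(3.0, 12.0, len(countries)),
        "fuel_price": rng.uniform(0.5, 1.5, len(countries)),       # currency/L
        "timber_export_price": rng.uniform(30.0, 120.0, len(countries)),  # /m^3
        "carcass_efficiency": rng.uniform(0.15, 0.3, len(countries)),     # t/head
        "fertilizer_price": rng.uniform(0.3, 1.0, len(countries)), # currency/kg
        "commercial_fraction": rng.uniform(0.2, 0.4, len(countries)),
    }, index=pd.Index(countries, name="country_id"))

    n_days = 1300  # ~daily series Aug 2011 - Oct 2016
    prices = rng.normal(13.6, 2.0, n_days)
    prices = np.maximum(prices - prices.mean() + 13.6, 0.1)
    carbon_market = pd.DataFrame({
        "date": pd.date_range("2011-08-01", periods=n_days, freq="D").astype(str),
        "price": prices,
    })

    # 5 emissions scenarios x 1,000 observations, lognormal damages
    sigma = 0.47
    pool = rng.lognormal(np.log(30.0) - sigma ** 2 / 2.0, sigma, 5000)
    pool *= 30.0 / pool.mean()

    internalization = pd.DataFrame({
        "person_hours": [0.5, 1.0, 1.5, 1.0, 0.8, 0.7],
    }, index=pd.Index(INTERNALIZATION_CATEGORIES, name="category"))

    fallback = {int(c): int((c + 1) % config.n_countries) for c in countries}
    return EconTables(
        crop_prices=crop_prices,
        crop_params=crop_params,
        country_params=country_params,
        carbon_market=carbon_market,
        scc_pool=pool,
        internalization=internalization,
        price_fallback_country=fallback,
    )


def true_tev_grid(grid: LandscapeGrid, truth: SynthTruth,
                  multipliers: dict[str, float]) -> np.ndarray:
    """Noise-free per-cell TEV implied by the generative truth.

    Mirrors the prediction convention: one log prediction per valuation
    method, averaged across the three methods per ES class, back-transformed,
    then combined with the ES-class multipliers.  Realized country effects
    are included (they are part of the generating process).
    """
    newdata = grid_newdata(grid)
    builder = truth.builder
    effects = newdata["country"].map(truth.country_effects).fillna(0.0).to_numpy()
    tev = np.zeros(len(newdata))
    for es_class, mult in multipliers.items():
        log_preds = []
        for method in METHOD_LEVELS:
            nd = newdata.assign(es_class=es_class, method_class=method)
            X, cols = builder.transform(nd, allow_mean_fill=True)
            log_preds.append(X @ beta_vector(truth.beta, cols) + effects)
        tev += mult * np.exp(np.mean(log_preds, axis=0))
    return tev.reshape(grid.shape)


def grid_newdata(grid: LandscapeGrid) -> pd.DataFrame:
    """Per-cell covariate table in row-major cell order."""
    out = {"country": grid.flat("country_id").astype(int)}
    for cov in list(COVARIATE_RANGES) + ["protected_area"]:
        out[cov] = grid.flat(cov)
    frame = pd.DataFrame(out)
    frame["peer_reviewed"] = 1.0  # predictions for peer-reviewed-style studies
    return frame
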