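"""Joint Monte Carlo propagation of all uncertainty sources.

Each replicate draws one bootstrap ES-value surface, perturbs the
forest-loss map to its classification accuracies (a loss cell stays loss
with p = 0.87; a no-loss cell flips with p = 0.003 and receives its
country's mean loss area), samples the market carbon price from the daily
series, the social price from the damage-draw pool, each crop-country price
from its Normal(mean, sd) truncated at zero, and — for the national-crop
scenarios — redraws the crop assignment.  One master seed spawns an
independent stream per (source, replicate), so switching any one source off
leaves every other source's draws unchanged.

The replicate ensemble reduces to empirical percentile maps and tables
(linear-interpolation quantile definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .agrorent import assign_crops, rent_map
from .carbonval import (DEFAULT_PEAT_C_PER_M, CarbonPools, annualize,
                        cell_emissions, price_emissions)
from .config import (DEFAULT_MULTIPLIERS, CarbonPriceModel, ScenarioSpec,
                     UncertaintySpec)
from .econ import EconTables
from .esmeta.bootstrap import ESMapEnsemble
from .exceptions import TevTradeError
from .grid import LandscapeGrid
from .tradeoff import internalization_map

__all__ = ["PriceDraw", "OutcomeEnsemble", "perturb_loss_map",
           "sample_prices", "run_monte_carlo", "reduce_percentiles",
           "MonteCarloEngine"]


@dataclass
class PriceDraw:
    """One replicate's price draws."""

    carbon_market: float
    carbon_social: float
    crop: dict[tuple[str, int], float] | None  # None -> table means


def perturb_loss_map(loss_map: np.ndarray, spec: UncertaintySpec,
                     rng: np.random.Generator,
                     country_id: np.ndarray | None = None) -> np.ndarray:
    """Stochastic loss map honouring the classification accuracies.

    Loss cells are zeroed with probability ``1 - loss_accuracy``; no-loss
    cells become loss with probability ``1 - noloss_accuracy`` and are
    assigned the mean loss area of their country's loss cells (the global
    mean when no country map is supplied or a country has no loss).
    """
    loss = np.asarray(loss_map, dtype=float)
    out = loss.copy()
    is_loss = loss > 0
    drop = is_loss & (rng.random(loss.shape) >= spec.loss_accuracy)
    out[drop] = 0.0
    flip = (~is_loss) & (rng.random(loss.shape) >= spec.noloss_accuracy)
    if flip.any():
        global_mean = loss[is_loss].mean() if is_loss.any() else 0.0
        if country_id is None:
            out[flip] = global_mean
        else:
            country_id = np.asarray(country_id).astype(int)
            fill = np.full(loss.shape, global_mean)
            for c in np.unique(country_id):
                mask = (country_id == c) & is_loss
                if mask.any():
                    fill[country_id == c] = loss[mask].mean()
            out[flip] = fill[flip]
    return out


def sample_prices(econ: EconTables, spec: UncertaintySpec,
                  rep: int = 0, master_seed: int | None = None) -> PriceDraw:
    """Draw one replicate's prices from their uncertainty distributions.

    Inactive sources collapse to their central values (series mean, pool
    mean, table means).
    """
    seed = spec.seed if master_seed is None else master_seed
    series = econ.carbon_market["price"].to_numpy()
    if spec.active("carbon_market"):
        rng = stream(seed, "carbon_market", rep)
        carbon_market = float(series[rng.integers(0, len(series))])
    else:
        carbon_market = float(series.mean())
    if spec.active("carbon_social"):
        rng = stream(seed, "carbon_social", rep)
        carbon_social = float(econ.scc_pool[rng.integers(0, len(econ.scc_pool))])
    else:
        carbon_social = float(econ.scc_pool.mean())
    crop_draw = None
    if spec.active("crop_prices"):
        rng = stream(seed, "crop_prices", rep)
        crop_draw = {}
        for row in econ.crop_prices.itertuples(index=False):
            value = rng.normal(row.mean, row.sd) if row.sd > 0 else row.mean
            crop_draw[(row.crop, int(row.country_id))] = max(float(value), 0.0)
    return PriceDraw(carbon_market=carbon_market, carbon_social=carbon_social,
                     crop=crop_draw)


@dataclass
class OutcomeEnsemble:
    """M Monte Carlo replicates of impact maps and aggregate tables."""

    impact_maps: np.ndarray          # (M, ny, nx), currency/yr per cell
    aggregates: pd.DataFrame         # one row per replicate
    country_aggregates: pd.DataFrame  # (rep, country_id) impact/tev/ar totals
    spec: UncertaintySpec
    scenario_id: str
    n_failed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.impact_maps.shape[0]

    def percentile_maps(self, probs=(2.5, 50.0, 97.5)) -> dict[float, np.ndarray]:
        return {p: np.percentile(self.impact_maps, p, axis=0) for p in probs}

    def percentile_table(self, probs=(2.5, 50.0, 97.5)) -> pd.DataFrame:
        numeric = self.aggregates.select_dtypes("number")
        return pd.DataFrame({f"p{p}": numeric.quantile(p / 100.0) for p in probs})


def reduce_percentiles(ensemble: OutcomeEnsemble,
                       probs=(2.5, 50.0, 97.5)) -> dict:
    """Empirical percentile maps and aggregate tables of an ensemble."""
    return {"maps": ensemble.percentile_maps(probs),
            "table": ensemble.percentile_table(probs)}


class MonteCarloEngine:
    """Orchestrates the per-replicate computation of net impacts."""

    def __init__(self, grid: LandscapeGrid, es_ensemble: ESMapEnsemble,
                 econ: EconTables, scenario: ScenarioSpec | str,
                 spec: UncertaintySpec | None = None,
                 carbon_model: CarbonPriceModel | None = None,
                 multipliers: dict[str, float] | None = None,
                 apply_internalization: bool = True,
                 peat_c_per_m: float = DEFAULT_PEAT_C_PER_M,
                 impact_mode: str = "tev_market"):
        if isinstance(scenario, str):
            scenario = ScenarioSpec.from_id(scenario)
        self.grid = grid
        self.es_ensemble = es_ensemble
        self.econ = econ
        self.scenario = scenario
        self.spec = spec or UncertaintySpec()
        self.carbon = carbon_model or CarbonPriceModel()
        self.multipliers = multipliers or dict(DEFAULT_MULTIPLIERS)
        self.apply_internalization = apply_internalization
        self.impact_mode = impact_mode  # {"tev_market", "tev_social", "carbon_market", "carbon_social"}

        pools = CarbonPools(agb_c=grid.layer("agb_carbon"),
                            bgb_c=grid.layer("bgb_carbon"),
                            dom_c=grid.layer("dom_carbon"),
                            peat_depth=grid.layer("peat_depth"),
                            peat_c_per_m=peat_c_per_m)
        self._emissions = cell_emissions(pools)          # tCO2e/ha
        self._intern = (internalization_map(econ, grid)
                        if apply_internalization else np.zeros(grid.shape))
        self._country = grid.layer("country_id").astype(int)
        # fixed crop assignment for the ablated national-sample path
        self._fixed_assignment = None
        if (self.scenario.crop_source == "national_sample"
                and not self.spec.active("crop_assignment")):
            self._fixed_assignment = assign_crops(
                grid, self.scenario, econ,
                rng=stream(self.spec.seed, "crop_assignment_fixed"))

    # -- one replicate ----------------------------------------------------
    def _replicate(self, m: int):
        spec, grid = self.spec, self.grid
        if self.spec.active("es_bootstrap"):
            rng = stream(spec.seed, "es_pick", m)
            es_map = self.es_ensemble.maps[rng.integers(0, self.es_ensemble.B)]
        else:
            es_map = self.es_ensemble.point_map

        rng = stream(spec.seed, "loss_map", m)
        loss = perturb_loss_map(grid.layer("forest_loss_area"), spec, rng,
                                country_id=self._country)

        draw = sample_prices(self.econ, spec, rep=m)

        assignment = self._fixed_assignment
        rng_crops = None
        if (self.scenario.crop_source == "national_sample"
                and assignment is None):
            rng_crops = stream(spec.seed, "crop_assignment", m)
        ar, _ = rent_map(grid, self.scenario, self.econ, rng=rng_crops,
                         prices=draw.crop, assignment=assignment,
                         loss_area=loss, r=self.carbon.discount_rate,
                         T=self.carbon.horizon)

        def carbon_value(price: float) -> np.ndarray:
            one_off = price_emissions(self._emissions, price,
                                      basis=self.carbon.price_basis)
            return annualize(one_off, self.carbon.discount_rate,
                             self.carbon.horizon)

        carbon_m = carbon_value(draw.carbon_market)
        carbon_s = carbon_value(draw.carbon_social)

        externality = {
            "tev_market": es_map - self._intern + carbon_m,
            "tev_social": es_map - self._intern + carbon_s,
            "carbon_market": carbon_m,
            "carbon_social": carbon_s,
        }[self.impact_mode]
        impact = (externality - ar) * loss

        agg = {
            "ar_total": float((ar * loss).sum()),
            "es_total": float((es_map * loss).sum()),
            "carbon_market_total": float((carbon_m * loss).sum()),
            "carbon_social_total": float((carbon_s * loss).sum()),
            "internalization_total": float((self._intern * loss).sum()),
            "loss_area_total": float(loss.sum()),
            "impact_total": float(impact.sum()),
        }
        agg["tev_market_total"] = (agg["es_total"] + agg["carbon_market_total"]
                                   - agg["internalization_total"])
        agg["tev_social_total"] = (agg["es_total"] + agg["carbon_social_total"]
                                   - agg["internalization_total"])

        country_rows = []
        for c in np.unique(self._country):
            mask = self._country == c
            country_rows.append({
                "country_id": int(c),
                "impact_total": float(impact[mask].sum()),
                "tev_total": float((externality * loss)[mask].sum()),
                "ar_total": float((ar * loss)[mask].sum()),
            })
        return impact, agg, country_rows

    def run(self) -> OutcomeEnsemble:
        M = self.spec.n_reps
        maps = np.empty((M,) + self.grid.shape)
        agg_rows, country_rows = [], []
        n_failed = 0
        for m in range(M):
            try:
                impact, agg, crows = self._replicate(m)
            except TevTradeError as exc:
                n_failed += 1
                if n_failed > max(1, M // 10):
                    raise TevTradeError(
                        f"more than 10% of replicates failed (last: {exc})"
                    ) from exc
                impact, agg, crows = self._replicate(m)  # one retry
            maps[m] = impact
            agg["rep"] = m
            agg_rows.append(agg)
            for row in crows:
                row["rep"] = m
                country_rows.append(row)
        return OutcomeEnsemble(
            impact_maps=maps,
            aggregates=pd.DataFrame(agg_rows),
            country_aggregates=pd.DataFrame(country_rows),
            spec=self.spec,
            scenario_id=self.scenario.id,
            n_failed=n_failed,
            meta={"impact_mode": self.impact_mode,
                  "price_basis": self.carbon.price_basis},
        )


def run_monte_carlo(grid: LandscapeGrid, es_ensemble: ESMapEnsemble,
                    econ: EconTables, scenario: ScenarioSpec | str,
                    spec: UncertaintySpec | None = None,
                    **kwargs) -> OutcomeEnsemble:
    """Functional front end to :class:`MonteCarloEngine`."""
    return MonteCarloEngine(grid, es_ensemble, econ, scenario, spec,
                            **kwargs).run()
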