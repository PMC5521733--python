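"""Per-cell annual net agricultural rents under scenarios A-D.

The rent of a deforested cell is the classic land-rent identity
``AR = y * p - c``: yield times farm-gate price minus production costs
(labour, fertilizer and — for the maximum-rent cash-crop scenarios —
transport to market, costed as a one-driver truck that returns empty).
Scenarios A/B draw the replacing crop from the country's area-weighted crop
composition (cattle included via pasture); scenarios C/D assign the crop
with the highest potential net rent per cell, using potential yields and
full costs.  Gross scenarios (B, D) report the same conversion without
deducting production costs.  A one-off timber windfall from the cleared
stock is annualized and added to every deforested cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import stream
from .carbonval import annualize
from .config import CATTLE, ScenarioSpec, TruckParams
from .econ import EconTables
from .exceptions import ConfigurationError
from .grid import LandscapeGrid

__all__ = ["CostComponents", "transport_cost", "production_costs", "net_rent",
           "timber_rent", "cattle_rent", "assign_crops", "rent_map",
           "candidate_crops"]


@dataclass
class CostComponents:
    """Annual production costs per hectare, by component."""

    transport: float = 0.0
    labor: float = 0.0
    fertilizer: float = 0.0

    @property
    def total(self) -> float:
        return self.transport + self.labor + self.fertilizer


def transport_cost(travel_time: float, wage_hour: float, fuel_price: float,
                   truck: TruckParams | None = None) -> float:
    """Cost (currency/t) of trucking produce to the nearest market.

    Round trip at the truck's average speed, fuel burned over the full
    distance, one driver paid for the round trip, the truck returning empty.
    """
    truck = truck or TruckParams()
    if truck.capacity_m3 <= 0:
        raise ConfigurationError("truck capacity must be > 0")
    round_trip_km = 2.0 * travel_time * truck.speed_kmh
    cost_per_load = (round_trip_km * truck.fuel_l_per_km * fuel_price
                     + 2.0 * travel_time * wage_hour)
    return cost_per_load / (truck.capacity_m3 * truck.density_t_per_m3)


def production_costs(crop: str, country: int, econ: EconTables,
                     scenario: ScenarioSpec, yield_t: float,
                     travel_time: float, fertilizer_usage: float,
                     ) -> CostComponents:
    """Annual per-hectare production costs of one crop in one cell.

    Scenario A deducts labour and fertilizer; scenario C additionally
    deducts transport for transported (cash) crops.  The gross scenarios
    B and D deduct nothing.
    """
    if not scenario.deduct_costs:
        return CostComponents()
    labor = econ.persondays(crop) * econ.wage_day(country)
    fertilizer = (0.0 if crop == CATTLE
                  else fertilizer_usage * econ.country_value(country, "fertilizer_price"))
    transport = 0.0
    if (scenario.crop_source == "max_rent" and crop != CATTLE
            and econ.is_transported(crop)):
        transport = transport_cost(
            travel_time, econ.wage_hour(country),
            econ.country_value(country, "fuel_price"), econ.truck) * yield_t
    return CostComponents(transport=transport, labor=labor, fertilizer=fertilizer)


def net_rent(yield_t: float, price: float, costs: float) -> float:
    """AR = y*p - c (currency/ha/yr); negative rents are preserved."""
    if np.any(np.asarray(yield_t) < 0) or np.any(np.asarray(price) < 0):
        raise ConfigurationError("yield and price must be >= 0")
    out = np.asarray(yield_t) * np.asarray(price) - np.asarray(costs)
    return float(out) if np.ndim(out) == 0 else out


def timber_rent(growing_stock: float, commercial_fraction: float,
                export_price: float, r: float = 0.05, T: float = 100.0):
    """Annualized one-off timber windfall (currency/ha/yr)."""
    if np.any((np.asarray(commercial_fraction) < 0)
              | (np.asarray(commercial_fraction) > 1)):
        raise ConfigurationError("commercial_fraction must lie in [0, 1]")
    one_off = (np.asarray(growing_stock) * np.asarray(commercial_fraction)
               * np.asarray(export_price))
    return annualize(one_off, r, T)


def cattle_rent(stocking: float, carcass_eff: float, price: float,
                costs: float = 0.0):
    """Annual cattle rent: stocking x carcass efficiency x price - costs."""
    out = (np.asarray(stocking) * np.asarray(carcass_eff) * np.asarray(price)
           - np.asarray(costs))
    return float(out) if np.ndim(out) == 0 else out


def candidate_crops(grid: LandscapeGrid) -> tuple[str, ...]:
    """The crop set a cell can be converted to: grid crops plus cattle."""
    return tuple(grid.crops) + (CATTLE,)


def _price_matrix(econ: EconTables, crops: tuple[str, ...],
                  countries: np.ndarray,
                  draw: dict[tuple[str, int], float] | None) -> np.ndarray:
    """(n_crops, n_countries) prices; ``draw`` overrides the table means."""
    out = np.zeros((len(crops), len(countries)))
    for i, crop in enumerate(crops):
        for j, country in enumerate(countries):
            if draw is not None and (crop, int(country)) in draw:
                out[i, j] = draw[(crop, int(country))]
            else:
                out[i, j] = econ.price(crop, int(country))[0]
    return out


def _rent_components(grid: LandscapeGrid, scenario: ScenarioSpec,
                     econ: EconTables,
                     prices: dict[tuple[str, int], float] | None):
    """Per-candidate-crop gross rents and costs, vectorized over cells.

    Returns (crops, gross, costs) with gross/costs of shape
    (n_candidates, n_cells); costs are the full (net-rent) costs regardless
    of ``deduct_costs`` — the caller decides whether to deduct.
    """
    crops = candidate_crops(grid)
    countries = grid.countries
    code = np.searchsorted(countries, grid.flat("country_id").astype(int))
    n_cells = grid.n_cells

    price = _price_matrix(econ, crops, countries, prices)
    wage_day = np.array([econ.wage_day(int(c)) for c in countries])
    wage_hour = np.array([econ.wage_hour(int(c)) for c in countries])
    fuel = np.array([econ.country_value(int(c), "fuel_price") for c in countries])
    fert_price = np.array([econ.country_value(int(c), "fertilizer_price")
                           for c in countries])
    carcass = np.array([econ.country_value(int(c), "carcass_efficiency")
                        for c in countries])

    travel = grid.flat("travel_time")
    fert_usage = grid.flat("fertilizer_usage")
    stocking = grid.flat("cattle_stocking")
    truck = econ.truck
    # per-cell transport cost per tonne (country wages/fuel, cell travel time)
    tcost_per_t = ((2.0 * travel * truck.speed_kmh * truck.fuel_l_per_km
                    * fuel[code]) + 2.0 * travel * wage_hour[code]) / (
                       truck.capacity_m3 * truck.density_t_per_m3)

    yield_prefix = ("potential_yield_" if scenario.uses_potential_yield
                    else "yield_")
    gross = np.zeros((len(crops), n_cells))
    costs = np.zeros((len(crops), n_cells))
    for u, crop in enumerate(crops):
        if crop == CATTLE:
            gross[u] = stocking * carcass[code] * price[u, code]
            costs[u] = econ.persondays(CATTLE) * wage_day[code]
            continue
        y = grid.flat(yield_prefix + crop)
        gross[u] = y * price[u, code]
        costs[u] = (econ.persondays(crop) * wage_day[code]
                    + fert_usage * fert_price[code])
        if scenario.crop_source == "max_rent" and econ.is_transported(crop):
            costs[u] += tcost_per_t * y
    return crops, gross, costs


def assign_crops(grid: LandscapeGrid, scenario: ScenarioSpec, econ: EconTables,
                 rng: np.random.Generator | int | None = None,
                 prices: dict[tuple[str, int], float] | None = None,
                 loss_area: np.ndarray | None = None) -> np.ndarray:
    """Per-cell crop assignment (index into ``candidate_crops``; -1 = no loss).

    Scenarios A/B sample from the country's area-weighted crop composition
    (seeded); scenarios C/D take the argmax of potential net rent, ties
    broken by fixed crop order, deterministically.
    """
    if isinstance(rng, (int, np.integer)):
        rng = stream(int(rng), "crop_assignment")
    loss = grid.assert_same_geometry(
        loss_area if loss_area is not None else grid.layer("forest_loss_area"),
        "loss map").ravel()
    mask = loss > 0
    crops = candidate_crops(grid)
    assignment = np.full(grid.n_cells, -1, dtype=int)

    if scenario.crop_source == "national_sample":
        if rng is None:
            rng = stream(0, "crop_assignment")
        country_flat = grid.flat("country_id").astype(int)
        for country in grid.countries:
            cells = np.flatnonzero(mask & (country_flat == country))
            if cells.size == 0:
                continue
            if int(country) not in grid.crop_composition.index:
                raise ConfigurationError(
                    f"no crop composition for country {country}")
            weights = grid.crop_composition.loc[int(country)].reindex(
                list(crops)).fillna(0.0).to_numpy(dtype=float)
            if weights.sum() <= 0:
                raise ConfigurationError(
                    f"country {country} has no crops in its composition")
            assignment[cells] = rng.choice(
                len(crops), size=cells.size, p=weights / weights.sum())
    else:
        _, gross, costs = _rent_components(grid, scenario, econ, prices)
        rent = gross - costs  # argmax always over NET potential rent
        assignment[mask] = np.argmax(rent[:, mask], axis=0)
    return assignment.reshape(grid.shape)


def rent_map(grid: LandscapeGrid, scenario: ScenarioSpec, econ: EconTables,
             rng: np.random.Generator | int | None = None,
             prices: dict[tuple[str, int], float] | None = None,
             assignment: np.ndarray | None = None,
             loss_area: np.ndarray | None = None,
             include_timber: bool = True,
             r: float = 0.05, T: float = 100.0,
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell annual agricultural rent (currency/ha/yr) and crop assignment.

    Deforested cells carry the scenario's crop rent plus the annualized
    timber windfall; cells without forest loss carry zero.
    """
    loss = grid.assert_same_geometry(
        loss_area if loss_area is not None else grid.layer("forest_loss_area"),
        "loss map").ravel()
    mask = loss > 0
    if assignment is None:
        assignment = assign_crops(grid, scenario, econ, rng=rng, prices=prices,
                                  loss_area=loss.reshape(grid.shape))
    assignment_flat = np.asarray(assignment).ravel()

    _, gross, costs = _rent_components(grid, scenario, econ, prices)
    rent_all = gross - costs if scenario.deduct_costs else gross

    ar = np.zeros(grid.n_cells)
    idx = np.flatnonzero(mask)
    ar[idx] = rent_all[assignment_flat[idx], idx]

    if include_timber:
        countries = grid.countries
        code = np.searchsorted(countries, grid.flat("country_id").astype(int))
        frac = np.array([econ.country_value(int(c), "commercial_fraction")
                         for c in countries])
        tprice = np.array([econ.country_value(int(c), "timber_export_price")
                           for c in countries])
        timber = timber_rent(grid.flat("growing_stock"), frac[code],
                             tprice[code], r=r, T=T)
        ar[idx] += timber[idx]
    return ar.reshape(grid.shape), assignment_flat.reshape(grid.shape)
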