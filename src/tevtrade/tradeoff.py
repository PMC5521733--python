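"""Integration of externalities and rents into net economic impacts.

The annual net impact of deforestation is ``I = sum_i (TEV_i - AR_i) A_i``:
per-cell externality value (total ES value including annualized carbon
emissions, minus the internalization cost of operating a payment-for-ES
program) minus agricultural rent, times the area deforested.  A carbon-only
mode substitutes the carbon value for TEV (without internalization, which
is a cost of internalizing ES value).  Aggregations to country and global
level conserve the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .econ import EconTables
from .exceptions import ConfigurationError, GeometryError
from .grid import LandscapeGrid

__all__ = ["ImpactGrid", "internalization_cost", "compute_impact",
           "aggregate", "cube_root_contrast", "signed_cbrt"]


@dataclass
class ImpactGrid:
    """Per-cell impact decomposition on a shared grid geometry."""

    tev: np.ndarray        # externality value used (currency/ha/yr)
    ar: np.ndarray         # agricultural rent (currency/ha/yr)
    area: np.ndarray       # deforested area (ha)
    impact: np.ndarray     # (tev - ar) * area (currency/yr)
    country_id: np.ndarray
    mode: str = "tev"

    def total(self) -> float:
        return float(self.impact.sum())


def internalization_cost(econ: EconTables, country: int,
                         hours_per_day: float = 8.0) -> float:
    """Annual per-hectare cost of operating ES-value internalization.

    Sum of the category person-hours (preparation, administration, community
    support, protected-area management, law enforcement, monitoring) priced
    at the country's hourly wage.
    """
    hours = float(econ.internalization["person_hours"].sum())
    return hours * econ.wage_hour(country, hours_per_day)


def internalization_map(econ: EconTables, grid: LandscapeGrid) -> np.ndarray:
    """(ny, nx) per-hectare internalization cost by cell country."""
    countries = grid.countries
    per_country = np.array([internalization_cost(econ, int(c)) for c in countries])
    code = np.searchsorted(countries, grid.flat("country_id").astype(int))
    return per_country[code].reshape(grid.shape)


def compute_impact(tev_map: np.ndarray, ar_map: np.ndarray,
                   grid: LandscapeGrid,
                   internalization: np.ndarray | float = 0.0,
                   carbon_map: np.ndarray | None = None,
                   loss_area: np.ndarray | None = None,
                   mode: str = "tev") -> ImpactGrid:
    """Per-cell net impact grid.

    ``mode='tev'``: externality = TEV + carbon (if given) - internalization.
    ``mode='carbon'``: externality = carbon value alone (internalization is
    not applied; it is a cost of internalizing ES value).
    """
    if mode not in ("tev", "carbon"):
        raise ConfigurationError(f"unknown impact mode {mode!r}")
    tev_map = grid.assert_same_geometry(tev_map, "TEV map")
    ar_map = grid.assert_same_geometry(ar_map, "AR map")
    if carbon_map is not None:
        carbon_map = grid.assert_same_geometry(carbon_map, "carbon map")
    area = grid.assert_same_geometry(
        loss_area if loss_area is not None else grid.layer("forest_loss_area"),
        "loss map")
    if np.ndim(internalization):
        internalization = grid.assert_same_geometry(
            internalization, "internalization map")

    if mode == "carbon":
        if carbon_map is None:
            raise ConfigurationError("carbon-only mode requires a carbon map")
        externality = carbon_map
    else:
        externality = tev_map - internalization
        if carbon_map is not None:
            externality = externality + carbon_map
    impact = (externality - ar_map) * area
    return ImpactGrid(tev=externality, ar=ar_map, area=area, impact=impact,
                      country_id=grid.layer("country_id").astype(int),
                      mode=mode)


def aggregate(impact: ImpactGrid, level: str = "global") -> pd.DataFrame:
    """Sum impacts at cell, country, or global level.

    The global total equals the sum of country totals exactly (conservation).
    """
    frame = pd.DataFrame({
        "country_id": impact.country_id.ravel(),
        "impact_total": impact.impact.ravel(),
        "tev_total": (impact.tev * impact.area).ravel(),
        "ar_total": (impact.ar * impact.area).ravel(),
        "area": impact.area.ravel(),
    })
    if level == "cell":
        return frame.reset_index(names="cell_id")
    if level == "country":
        out = frame.groupby("country_id", as_index=False).sum()
        return out
    if level == "global":
        out = frame.drop(columns="country_id").sum().to_frame().T
        out.insert(0, "level", "global")
        return out
    raise ConfigurationError(f"unknown aggregation level {level!r}")


def signed_cbrt(x):
    """Sign-preserving cube root."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** (1.0 / 3.0)
    return float(out) if np.ndim(out) == 0 else out


def cube_root_contrast(tev_total, ar_total):
    """Cube-root-transformed externality-rent contrast: TEV^(1/3) - AR^(1/3).

    Negative totals (net-cost aggregates) use the signed cube root.
    """
    out = signed_cbrt(tev_total) - signed_cbrt(ar_total)
    return float(out) if np.ndim(out) == 0 else out
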