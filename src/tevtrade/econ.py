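"""Economic parameter tables: prices, wages, labour, carbon price draws.

Everything the valuation stages need that is not a raster lives here:
farm-gate crop prices per crop-country (mean and sd, for the price
uncertainty distributions), person-days of labour per crop, national wages
(agricultural with a manufacturing fallback), fuel and fertilizer prices,
timber export prices and carcass efficiencies, the daily market carbon-price
series, the social-cost-of-carbon draw pool, and the internalization cost
categories in person-hours.  Prices for crop-country combinations a country
does not grow fall back to a configured donor country, then to zero with a
warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TruckParams
from .exceptions import ConfigurationError

#: internalization cost categories (person-hours per hectare per year)
INTERNALIZATION_CATEGORIES = (
    "preparation", "administration", "community_support",
    "protected_area_management", "law_enforcement", "monitoring",
)


@dataclass
class EconTables:
    """All price/cost/wage parameters including uncertainty descriptors."""

    crop_prices: pd.DataFrame        # columns: crop, country_id, mean, sd
    crop_params: pd.DataFrame        # index crop: persondays, is_transported
    country_params: pd.DataFrame     # index country_id: wages, fuel, timber, ...
    carbon_market: pd.DataFrame      # columns: date, price (currency/t, daily)
    scc_pool: np.ndarray             # social-cost-of-carbon draws (currency/t)
    internalization: pd.DataFrame    # index category: person_hours (per ha/yr)
    truck: TruckParams = field(default_factory=TruckParams)
    price_fallback_country: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scc_pool = np.asarray(self.scc_pool, dtype=float)
        if len(self.carbon_market) == 0:
            raise ConfigurationError("carbon_market series must be non-empty")
        if self.scc_pool.size == 0:
            raise ConfigurationError("scc_pool must be non-empty")
        missing = set(INTERNALIZATION_CATEGORIES) - set(self.internalization.index)
        if missing:
            raise ConfigurationError(f"internalization table missing {sorted(missing)}")
        self._price_lut = self.crop_prices.set_index(["crop", "country_id"])

    # -- lookups ----------------------------------------------------------
    def price(self, crop: str, country: int) -> tuple[float, float]:
        """(mean, sd) farm-gate price with donor-country / zero fallback."""
        key = (crop, int(country))
        if key in self._price_lut.index:
            row = self._price_lut.loc[key]
            return float(row["mean"]), float(row["sd"])
        donor = self.price_fallback_country.get(int(country))
        if donor is not None and (crop, int(donor)) in self._price_lut.index:
            row = self._price_lut.loc[(crop, int(donor))]
            return float(row["mean"]), float(row["sd"])
        warnings.warn(
            f"no price for crop {crop!r} in country {country}; set to 0",
            stacklevel=2)
        return 0.0, 0.0

    def price_matrix(self, crops: tuple[str, ...], countries: np.ndarray,
                     which: str = "mean") -> np.ndarray:
        """(n_crops, n_countries) array of price means or sds."""
        out = np.zeros((len(crops), len(countries)))
        for i, crop in enumerate(crops):
            for j, country in enumerate(countries):
                mean, sd = self.price(crop, int(country))
                out[i, j] = mean if which == "mean" else sd
        return out

    def wage_day(self, country: int) -> float:
        """Daily wage: agricultural when available, else manufacturing."""
        row = self.country_params.loc[int(country)]
        wage = row.get("wage_agri_day", np.nan)
        if np.isnan(wage):
            wage = row.get("wage_manuf_day", np.nan)
        if np.isnan(wage):
            raise ConfigurationError(f"no wage available for country {country}")
        return float(wage)

    def wage_hour(self, country: int, hours_per_day: float = 8.0) -> float:
        return self.wage_day(country) / hours_per_day

    def country_value(self, country: int, column: str) -> float:
        try:
            return float(self.country_params.loc[int(country), column])
        except KeyError as exc:
            raise ConfigurationError(
                f"country {country} / column {column!r} missing from country table"
            ) from exc

    def persondays(self, crop: str) -> float:
        try:
            return float(self.crop_params.loc[crop, "persondays"])
        except KeyError as exc:
            raise ConfigurationError(f"no labour parameters for crop {crop!r}") from exc

    def is_transported(self, crop: str) -> bool:
        return bool(self.crop_params.loc[crop, "is_transported"])

    # -- serialization ----------------------------------------------------
    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.crop_prices.to_csv(path / "crop_prices.csv", index=False)
        self.crop_params.to_csv(path / "crop_params.csv")
        self.country_params.to_csv(path / "country_params.csv")
        self.carbon_market.to_csv(path / "carbon_market.csv", index=False)
        pd.DataFrame({"draw": self.scc_pool}).to_csv(path / "scc_pool.csv", index=False)
        self.internalization.to_csv(path / "internalization.csv")
        meta = {
            "truck": self.truck.__dict__,
            "price_fallback_country": {str(k): v for k, v in
                                       self.price_fallback_country.items()},
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read_dir(cls, path: str | Path) -> "EconTables":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        return cls(
            crop_prices=pd.read_csv(path / "crop_prices.csv"),
            crop_params=pd.read_csv(path / "crop_params.csv", index_col=0),
            country_params=pd.read_csv(path / "country_params.csv", index_col=0),
            carbon_market=pd.read_csv(path / "carbon_market.csv"),
            scc_pool=pd.read_csv(path / "scc_pool.csv")["draw"].to_numpy(),
            internalization=pd.read_csv(path / "internalization.csv", index_col=0),
            truck=TruckParams(**meta["truck"]),
            price_fallback_country={int(k): int(v) for k, v in
                                    meta["price_fallback_country"].items()},
        )
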