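"""Configuration objects for the synthetic study system and the pipeline.

The synthetic-data generator emulates a pantropical 0.1-degree analysis grid:
per-cell forest loss 2000-2012, biomass carbon pools, peat, crop yields and
socio-environmental covariates, together with a valuation-study table and the
economic parameter tables (prices, wages, carbon price series) that the
downstream valuation stages consume.  All defaults below are the study
conditions; tests and the acceptance script run under them unless a scaled
problem size is stated explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

from .exceptions import ConfigurationError

# The 18 major tropical crops (top 10 by area and by production value,
# union) plus cattle, which enters the crop list for pasture conversion.
DEFAULT_CROPS: tuple[str, ...] = (
    "banana", "bean", "cassava", "cocoa", "coconut", "coffee", "cotton",
    "cowpea", "groundnut", "maize", "millet", "oil_palm", "rice", "rubber",
    "sorghum", "soybean", "sugar_cane", "wheat",
)
CATTLE = "cattle"

# Generative coefficients of the ES-value model on the natural-log scale.
# Factors: ES class (baseline cultural) and valuation method (baseline
# cost-based), exactly the two clustered 3-level predictors of the fitted
# model; continuous covariates act on the z-score scale.
DEFAULT_TRUE_BETA: dict[str, float] = {
    "intercept": 5.0,
    "es_class[provisioning]": 0.6,
    "es_class[regulating]": 0.8,
    "method_class[revealed]": -0.7,
    "method_class[stated]": 0.9,
    "temperature": 0.6,
    "year": -0.5,
    "richness_birds": -0.55,
}

#: continuous record/grid covariates available as model predictors
COVARIATES: tuple[str, ...] = (
    "temperature", "precipitation", "accessibility", "population",
    "altitude", "gdp", "protected_area", "richness_birds",
    "richness_amphibians", "richness_mammals", "richness_plants",
    "carbon_density",
)

#: default candidate terms for model enumeration (8 free terms -> 256 models)
DEFAULT_CANDIDATE_TERMS: tuple[str, ...] = (
    "es_class", "method_class", "peer_reviewed", "year",
    "temperature", "precipitation", "accessibility", "richness_birds",
)


@dataclass
class SynthConfig:
    """Ground-truth parameters of the synthetic study system."""

    grid_nx: int = 50
    grid_ny: int = 50
    cell_area: float = 12_000.0          # ha per cell (~0.1 deg at the equator)
    n_countries: int = 5
    true_beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    sigma_country: float = 0.5           # sd of country random intercept (log scale)
    sigma_resid: float = 1.0             # residual sd (log scale)
    n_records: int = 78                  # valuation observations (30 studies)
    n_studies: int = 30
    crop_set: tuple[str, ...] = DEFAULT_CROPS
    price_cv: float = 0.15               # coefficient of variation of crop prices
    peat_fraction: float = 0.1           # proportion of cells on peat
    peat_depth_mean: float = 3.0         # m, exponential mean
    peat_depth_max: float = 12.0         # m, truncation
    forest_loss_fraction: float = 0.3    # proportion of cells with loss
    collinear_covariate: str | None = None   # duplicate this covariate + noise
    collinear_noise_sd: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.crop_set = tuple(self.crop_set)
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ConfigurationError("grid_nx/grid_ny must be >= 1")
        if self.cell_area <= 0:
            raise ConfigurationError("cell_area must be > 0")
        if self.n_countries < 1:
            raise ConfigurationError("n_countries must be >= 1")
        if self.n_countries > self.grid_nx * self.grid_ny:
            raise ConfigurationError("n_countries exceeds grid cell count")
        for name in ("sigma_country", "sigma_resid", "price_cv",
                     "peat_depth_mean", "peat_depth_max"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("peat_fraction", "forest_loss_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_records < 1:
            raise ConfigurationError("n_records must be >= 1")
        if not self.crop_set:
            raise ConfigurationError("crop_set must be non-empty")

    @property
    def n_cells(self) -> int:
        return self.grid_nx * self.grid_ny

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ScenarioSpec:
    """Crop-replacement scenario.

    A: national crop composition, production costs deducted (net rents).
    B: national crop composition, gross rents (no costs).
    C: per-cell maximum-potential-rent crop, costs deducted.
    D: per-cell maximum-potential-rent crop, gross rents.
    """

    id: str
    crop_source: str      # {"national_sample", "max_rent"}
    deduct_costs: bool

    _TABLE = {
        "A": ("national_sample", True),
        "B": ("national_sample", False),
        "C": ("max_rent", True),
        "D": ("max_rent", False),
    }

    def __post_init__(self) -> None:
        if self.id not in self._TABLE:
            raise ConfigurationError(f"unknown scenario id {self.id!r} (must be A-D)")
        src, ded = self._TABLE[self.id]
        if (self.crop_source, self.deduct_costs) != (src, ded):
            raise ConfigurationError(
                f"scenario {self.id} must be crop_source={src!r}, deduct_costs={ded}")

    @classmethod
    def from_id(cls, scenario_id: str) -> "ScenarioSpec":
        scenario_id = str(scenario_id).upper()
        if scenario_id not in cls._TABLE:
            raise ConfigurationError(f"unknown scenario id {scenario_id!r} (must be A-D)")
        src, ded = cls._TABLE[scenario_id]
        return cls(scenario_id, src, ded)

    @property
    def uses_potential_yield(self) -> bool:
        return self.crop_source == "max_rent"


@dataclass(frozen=True)
class TruckParams:
    """Transport assumptions: one truck, one driver, empty return trip."""

    capacity_m3: float = 18.0
    speed_kmh: float = 45.0
    fuel_l_per_km: float = 0.3
    density_t_per_m3: float = 1.0

    def __post_init__(self) -> None:
        if self.capacity_m3 <= 0:
            raise ConfigurationError("truck capacity_m3 must be > 0")
        for name in ("speed_kmh", "fuel_l_per_km", "density_t_per_m3"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"truck {name} must be >= 0")


@dataclass
class CarbonPriceModel:
    """Carbon pricing: market allowance series vs social-cost draw pool.

    ``price_basis`` states the unit the prices are quoted in.  The default is
    per tonne of CO2e; quoting per tonne of carbon multiplies values by 12/44
    at application time.
    """

    price_basis: str = "per_tCO2"        # {"per_tCO2", "per_tC"}
    discount_rate: float = 0.05
    horizon: float = 100.0

    def __post_init__(self) -> None:
        if self.price_basis not in ("per_tCO2", "per_tC"):
            raise ConfigurationError(f"unknown price_basis {self.price_basis!r}")
        if not 0.0 < self.discount_rate < 1.0:
            raise ConfigurationError("discount_rate must lie in (0, 1)")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1 year")


@dataclass
class UncertaintySpec:
    """Monte Carlo propagation settings.

    ``loss_accuracy`` / ``noloss_accuracy`` are the classification accuracies
    of the forest-loss map: a loss cell stays loss with p = 0.87 and a no-loss
    cell stays no-loss with p = 0.997 in every replicate.
    """

    n_reps: int = 200
    loss_accuracy: float = 0.87
    noloss_accuracy: float = 0.997
    sources: dict[str, bool] = field(default_factory=lambda: {
        "carbon_market": True,
        "carbon_social": True,
        "crop_prices": True,
        "es_bootstrap": True,
        "crop_assignment": True,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        for name in ("loss_accuracy", "noloss_accuracy"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        known = {"carbon_market", "carbon_social", "crop_prices",
                 "es_bootstrap", "crop_assignment"}
        unknown = set(self.sources) - known
        if unknown:
            raise ConfigurationError(f"unknown uncertainty sources: {sorted(unknown)}")
        for name in known:
            self.sources.setdefault(name, True)

    def active(self, source: str) -> bool:
        return bool(self.sources.get(source, True))


#: ES-class aggregation multipliers: 5 provisioning, 7 regulating minus the
#: one excluded to avoid double counting carbon, 5 cultural.
DEFAULT_MULTIPLIERS: dict[str, float] = {
    "provisioning": 5.0,
    "regulating": 6.0,
    "cultural": 5.0,
}


def validate_multipliers(multipliers: dict[str, float]) -> dict[str, float]:
    out = dict(DEFAULT_MULTIPLIERS)
    out.update(multipliers or {})
    for cls, value in out.items():
        if cls not in DEFAULT_MULTIPLIERS:
            raise ConfigurationError(f"unknown ES class {cls!r} in multipliers")
        if value < 0:
            raise ConfigurationError(f"multiplier for {cls!r} must be >= 0")
    return out
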