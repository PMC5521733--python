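"""Carbon-emission accounting and valuation.

Conversion of a forest cell releases the carbon held aboveground,
belowground and in dead organic matter, plus the peat carbon where forests
stand on peat soil; mineral soil carbon is conservatively assumed unchanged.
Stocks in tC/ha convert to CO2-equivalents with the molar factor 44/12.
Emissions are valued under two price regimes — the market allowance price
(reference 13.6 currency/t) and the social cost of carbon (reference mean
30 currency/t) — and the resulting one-off value is annualized with the
standard annuity factor (default 5% over 100 years).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["CarbonPools", "CO2_PER_C", "cell_emissions", "price_emissions",
           "annualize", "present_value"]

#: molar mass ratio CO2 / C
CO2_PER_C = 44.0 / 12.0

#: default peat carbon density per metre of depth (tC/ha/m); a free
#: parameter — peat depth maps carry no per-metre density of their own
DEFAULT_PEAT_C_PER_M = 500.0


@dataclass
class CarbonPools:
    """Per-hectare carbon stocks of one cell (tC/ha; peat depth in m)."""

    agb_c: float | np.ndarray = 0.0
    bgb_c: float | np.ndarray = 0.0
    dom_c: float | np.ndarray = 0.0
    peat_depth: float | np.ndarray = 0.0
    peat_c_per_m: float = DEFAULT_PEAT_C_PER_M

    def __post_init__(self) -> None:
        for name in ("agb_c", "bgb_c", "dom_c", "peat_depth"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ConfigurationError(f"carbon pool {name!r} must be >= 0")
        if self.peat_c_per_m < 0:
            raise ConfigurationError("peat_c_per_m must be >= 0")


def cell_emissions(pools: CarbonPools) -> float | np.ndarray:
    """CO2-equivalent emissions (tCO2e/ha) released by conversion."""
    total_c = (np.asarray(pools.agb_c) + np.asarray(pools.bgb_c)
               + np.asarray(pools.dom_c)
               + np.asarray(pools.peat_depth) * pools.peat_c_per_m)
    out = total_c * CO2_PER_C
    return float(out) if np.ndim(out) == 0 else out


def price_emissions(emissions, price: float,
                    basis: str = "per_tCO2"):
    """One-off value (currency/ha) of emissions at a carbon price.

    ``basis`` states the unit the price is quoted in: per tonne of CO2e
    (applied directly) or per tonne of carbon (scaled by 12/44).
    """
    if price < 0:
        raise ConfigurationError("carbon price must be >= 0")
    if basis == "per_tCO2":
        factor = 1.0
    elif basis == "per_tC":
        factor = 1.0 / CO2_PER_C
    else:
        raise ConfigurationError(f"unknown price basis {basis!r}")
    out = np.asarray(emissions) * price * factor
    return float(out) if np.ndim(out) == 0 else out


def annualize(pv, r: float, T: float):
    """Equivalent annual flow of a present value over T years at rate r.

    ``pv * r / (1 - (1+r)^-T)`` for r > 0, with the continuity limit
    ``pv / T`` at r = 0.
    """
    if r < 0:
        raise ConfigurationError("discount rate must be >= 0")
    if T < 1:
        raise ConfigurationError("horizon must be >= 1 year")
    pv = np.asarray(pv, dtype=float)
    if r == 0.0:
        out = pv / T
    else:
        out = pv * r / (1.0 - (1.0 + r) ** (-T))
    return float(out) if np.ndim(out) == 0 else out


def present_value(annual, r: float, T: float):
    """Discounted sum of T equal annual flows (the inverse of annualize)."""
    if r == 0.0:
        out = np.asarray(annual, dtype=float) * T
    else:
        out = np.asarray(annual, dtype=float) * (1.0 - (1.0 + r) ** (-T)) / r
    return float(out) if np.ndim(out) == 0 else out
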