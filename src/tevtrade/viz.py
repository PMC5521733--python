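"""Plots of the trade-off results.

Two standard views: the externality-versus-rent bar chart (median with
2.5th/97.5th percentile whiskers per quantity and scenario) and per-country
cube-root contrasts between externality value and agricultural rents.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mcengine import OutcomeEnsemble
from .tradeoff import signed_cbrt

__all__ = ["plot_externality_rent_bars", "plot_country_contrasts"]

_QUANTITIES = {
    "ar_total": "AGR",
    "carbon_market_total": "CO2m",
    "carbon_social_total": "CO2s",
    "tev_market_total": "TEVm",
    "tev_social_total": "TEVs",
}


def plot_externality_rent_bars(outcomes: dict[str, OutcomeEnsemble],
                               ax: plt.Axes | None = None) -> plt.Figure:
    """Median annual totals with 95% uncertainty whiskers per scenario.

    ``outcomes`` maps scenario id to its Monte Carlo ensemble; rents are
    shown per scenario, externalities from the first ensemble.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    labels, med, lo, hi = [], [], [], []
    for sid, ens in outcomes.items():
        values = ens.aggregates["ar_total"]
        labels.append(f"AGR{sid}")
        med.append(values.median())
        lo.append(np.percentile(values, 2.5))
        hi.append(np.percentile(values, 97.5))
    first = next(iter(outcomes.values()))
    for col, label in list(_QUANTITIES.items())[1:]:
        values = first.aggregates[col]
        labels.append(label)
        med.append(values.median())
        lo.append(np.percentile(values, 2.5))
        hi.append(np.percentile(values, 97.5))
    med, lo, hi = map(np.asarray, (med, lo, hi))
    x = np.arange(len(labels))
    ax.bar(x, med, color="tab:green", alpha=0.7)
    ax.errorbar(x, med, yerr=[med - lo, hi - med], fmt="none", ecolor="k",
                capsize=3)
    ax.set_xticks(x, labels)
    ax.set_ylabel("currency / yr")
    ax.set_title("Agricultural value gained vs externalities lost")
    return ax.figure


def plot_country_contrasts(outcomes: dict[str, OutcomeEnsemble],
                           ax: plt.Axes | None = None) -> plt.Figure:
    """Per-country cube-root contrast TEV^(1/3) - AR^(1/3) per scenario."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    width = 0.8 / max(len(outcomes), 1)
    for i, (sid, ens) in enumerate(outcomes.items()):
        grouped = ens.country_aggregates.groupby("country_id")
        med = grouped.median()
        contrast = signed_cbrt(med["tev_total"]) - signed_cbrt(med["ar_total"])
        # percentile whiskers over replicates, transformed after aggregation
        reps = ens.country_aggregates.assign(
            contrast=lambda d: signed_cbrt(d["tev_total"])
            - signed_cbrt(d["ar_total"]))
        lo = reps.groupby("country_id")["contrast"].quantile(0.025)
        hi = reps.groupby("country_id")["contrast"].quantile(0.975)
        x = np.arange(len(med)) + i * width
        mid = signed_cbrt(med["tev_total"]) - signed_cbrt(med["ar_total"])
        ax.bar(x, mid, width=width, label=f"scenario {sid}")
        ax.errorbar(x, mid, yerr=[np.maximum(mid - lo, 0),
                                  np.maximum(hi - mid, 0)],
                    fmt="none", ecolor="k", capsize=2)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("country")
    ax.set_ylabel("TEV$^{1/3}$ $-$ AR$^{1/3}$")
    ax.legend()
    return ax.figure
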