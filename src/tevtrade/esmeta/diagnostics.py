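"""Regression diagnostics for the meta-analytic model.

Collinearity is screened with variance inflation factors on the linear
fixed-effects analogue of the mixed model; heteroscedasticity with a
Breusch-Pagan test on the analogue that carries country as a fixed effect;
and residual spatial structure with an empirical semivariogram over binned
inter-point distances (a flat semivariogram — slope indistinguishable from
zero — indicates no spatial autocorrelation problem).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from ..design import DesignMatrixBuilder
from .predict import predict_single
from .selection import FittedModel, ModelSet

__all__ = ["DiagnosticsReport", "diagnostics", "vif_table", "semivariogram"]


@dataclass
class DiagnosticsReport:
    vif: pd.Series                 # per fixed-effect design column
    bp_pvalue: float
    semivariogram: pd.DataFrame    # columns: distance, gamma, n_pairs
    semivariogram_slope: float
    semivariogram_slope_se: float
    collinear_pairs: list[tuple[str, str]]

    def summary(self) -> str:
        lines = [f"max VIF: {self.vif.max():.2f} ({self.vif.idxmax()})",
                 f"Breusch-Pagan p-value: {self.bp_pvalue:.4f}",
                 (f"semivariogram slope: {self.semivariogram_slope:.4g} "
                  f"(se {self.semivariogram_slope_se:.4g})")]
        if self.collinear_pairs:
            lines.append(f"perfectly collinear pairs: {self.collinear_pairs}")
        return "\n".join(lines)


def vif_table(X: np.ndarray, columns: tuple[str, ...]) -> tuple[pd.Series, list]:
    """VIF per non-intercept column; perfectly collinear pairs reported."""
    keep = [j for j, c in enumerate(columns) if c != "intercept"]
    vifs = {}
    collinear: list[tuple[str, str]] = []
    corr = np.corrcoef(X[:, keep], rowvar=False) if len(keep) > 1 else np.ones((1, 1))
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            if abs(corr[a, b]) > 1.0 - 1e-12:
                collinear.append((columns[keep[a]], columns[keep[b]]))
    for j in keep:
        others = [o for o in range(X.shape[1]) if o != j]
        r2 = sm.OLS(X[:, j], X[:, others]).fit().rsquared
        vifs[columns[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs), collinear


def semivariogram(residuals: np.ndarray, x: np.ndarray, y: np.ndarray,
                  n_bins: int = 10) -> tuple[pd.DataFrame, float, float]:
    """Empirical semivariogram and the slope of gamma over distance."""
    residuals = np.asarray(residuals, dtype=float)
    coords = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n = len(residuals)
    ii, jj = np.triu_indices(n, k=1)
    dist = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    gamma_pair = 0.5 * (residuals[ii] - residuals[jj]) ** 2
    edges = np.linspace(0.0, dist.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        rows.append({"distance": dist[mask].mean(),
                     "gamma": gamma_pair[mask].mean(),
                     "n_pairs": int(mask.sum())})
    table = pd.DataFrame(rows)
    fit = sm.OLS(table["gamma"], sm.add_constant(table["distance"])).fit()
    return table, float(fit.params.iloc[1]), float(fit.bse.iloc[1])


def diagnostics(records: pd.DataFrame, model: FittedModel,
                model_set: ModelSet,
                x: np.ndarray | None = None, y: np.ndarray | None = None,
                n_bins: int = 10) -> DiagnosticsReport:
    """Full diagnostics report for one fitted model.

    ``x``/``y`` are per-record spatial coordinates; when omitted, the
    semivariogram is computed over (accessibility, altitude) space as a
    stand-in axis, which only exercises the machinery.
    """
    X, cols = model_set.builder.transform(records, terms=model.terms)
    vif, collinear = vif_table(X, cols)

    # Breusch-Pagan on the linear analogue with country as fixed effect
    country = pd.get_dummies(records["country"], prefix="country",
                             drop_first=True, dtype=float).to_numpy()
    exog = np.column_stack([X, country])
    ols = sm.OLS(records["log_value"].to_numpy(), exog).fit()
    bp_pvalue = float(het_breuschpagan(ols.resid, exog)[1])

    resid = records["log_value"].to_numpy() - predict_single(
        model, model_set, records, conditional=True)
    if x is None or y is None:
        x = records["accessibility"].to_numpy()
        y = records["altitude"].to_numpy()
    table, slope, slope_se = semivariogram(resid, x, y, n_bins=n_bins)
    return DiagnosticsReport(vif=vif, bp_pvalue=bp_pvalue,
                             semivariogram=table,
                             semivariogram_slope=slope,
                             semivariogram_slope_se=slope_se,
                             collinear_pairs=collinear)
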