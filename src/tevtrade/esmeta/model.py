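"""Statsmodels-style front end to the ES-value meta-analysis.

:class:`ESValueModel` is built from a screened valuation-record table;
``fit()`` enumerates all candidate term subsets, selects the high-support
set, and returns an :class:`ESValueResults` carrying the model set, the
conditionally averaged coefficients with uncertainties, and methods for
prediction, spatial TEV mapping, cross-validation, bootstrap uncertainty,
and diagnostics.

Example
-------
>>> model = ESValueModel(records)
>>> results = model.fit()
>>> print(results.summary())
>>> tev, components = results.predict_tev(grid)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..config import DEFAULT_CANDIDATE_TERMS
from ..grid import LandscapeGrid
from .bootstrap import ESMapEnsemble, bootstrap_es_maps
from .crossval import CVProcedure, CVResult, direct_benefit_transfer, loo_cv
from .diagnostics import DiagnosticsReport, diagnostics
from .predict import average_predict, predict_tev_grid
from .screening import ScreeningRules, screen_records
from .selection import ModelSet, enumerate_models, select_top

__all__ = ["ESValueModel", "ESValueResults"]


class ESValueModel:
    """Meta-analytic mixed model of per-hectare ES values.

    Parameters
    ----------
    records
        Screened valuation records with ``log_value``, ``country``, the two
        clustered factors (``es_class``, ``method_class``) and the covariate
        columns.
    candidate_terms
        Free fixed-effect terms to enumerate (2^J models; default 8 -> 256).
    cutoff
        AICc support cutoff for the averaged set (default 2).
    """

    def __init__(self, records: pd.DataFrame,
                 candidate_terms: tuple[str, ...] = DEFAULT_CANDIDATE_TERMS,
                 cutoff: float = 2.0):
        if "log_value" not in records.columns:
            records = records.copy()
            records["log_value"] = np.log(records["value"].to_numpy(dtype=float))
        self.records = records.reset_index(drop=True)
        self.candidate_terms = tuple(candidate_terms)
        self.cutoff = float(cutoff)

    @classmethod
    def from_csv(cls, path: str | Path, screen: bool = True,
                 rules: ScreeningRules | None = None, **kwargs) -> "ESValueModel":
        records = pd.read_csv(path)
        if screen:
            records, _ = screen_records(records, rules)
        return cls(records, **kwargs)

    def fit(self) -> "ESValueResults":
        model_set = enumerate_models(self.records, self.candidate_terms)
        top = select_top(model_set, self.cutoff)
        return ESValueResults(self, top)


class ESValueResults:
    """Fit results: the enumerated set, the averaged model, and tools."""

    def __init__(self, model: ESValueModel, top_set: ModelSet):
        self.model = model
        self.model_set = top_set
        self.params = self._average_params()

    # -- conditional averaging -------------------------------------------
    def _average_params(self) -> pd.DataFrame:
        """Conditional model-averaged coefficients over the top set.

        Each coefficient is averaged over the models that contain it, with
        renormalized Akaike weights; the unconditional-variance estimator
        adds the between-model spread to the within-model variance.  The
        ``importance`` column is the summed weight of the containing models.
        """
        top = self.model_set.top_models
        weights = self.model_set.top_weights
        columns: list[str] = []
        for m in top:
            for c in m.columns:
                if c not in columns:
                    columns.append(c)
        rows = []
        for col in columns:
            est, var, wsum, nmod = [], [], 0.0, 0
            for m, w in zip(top, weights):
                if col not in m.columns:
                    continue
                j = m.columns.index(col)
                est.append((w, m.fit.beta[j], m.fit.cov_beta[j, j]))
                wsum += w
                nmod += 1
            avg = sum(w * b for w, b, _ in est) / wsum
            uncond = np.sqrt(sum(w * (v + (b - avg) ** 2)
                                 for w, b, v in est) / wsum)
            rows.append({"term": col, "estimate": avg, "se": uncond,
                         "importance": wsum, "n_models": nmod})
        return pd.DataFrame(rows).set_index("term")

    @property
    def top_models(self):
        return self.model_set.top_models

    @property
    def top_weights(self) -> np.ndarray:
        return self.model_set.top_weights

    @property
    def n_top(self) -> int:
        return len(self.model_set.top_models)

    # -- prediction ------------------------------------------------------
    def predict(self, newdata: pd.DataFrame, mode: str = "conditional") -> np.ndarray:
        """Model-averaged log-value prediction per row."""
        return average_predict(self.model_set, newdata, mode=mode)

    def predict_tev(self, grid: LandscapeGrid,
                    multipliers: dict[str, float] | None = None,
                    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Per-cell TEV surface and ES-class components."""
        return predict_tev_grid(self.model_set, grid, multipliers)

    def bootstrap_maps(self, grid: LandscapeGrid, B: int = 500, seed: int = 0,
                       **kwargs) -> ESMapEnsemble:
        return bootstrap_es_maps(self.model.records, grid, B=B, seed=seed,
                                 candidate_terms=self.model.candidate_terms,
                                 cutoff=self.model.cutoff,
                                 top_set=self.model_set, **kwargs)

    # -- validation ------------------------------------------------------
    def loo_cv(self, candidate_terms: tuple[str, ...] | None = None) -> CVResult:
        procedure = CVProcedure(candidate_terms or self.model.candidate_terms,
                                self.model.cutoff)
        return loo_cv(self.model.records, procedure)

    def direct_benefit_transfer(self, level: str = "global") -> CVResult:
        return direct_benefit_transfer(self.model.records, level=level)

    def diagnostics(self, which: int = 0, **kwargs) -> DiagnosticsReport:
        """Diagnostics for the ``which``-th top model (0 = best)."""
        return diagnostics(self.model.records,
                           self.model_set.top_models[which],
                           self.model_set, **kwargs)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        best = self.model_set.best
        lines = [
            "ES-value meta-analytic mixed model (ML, AICc model averaging)",
            "=" * 62,
            f"records: {len(self.model.records)}   "
            f"countries: {self.model.records['country'].nunique()}",
            f"models enumerated: {self.model_set.n_models}   "
            f"high-support (dAICc <= {self.model_set.cutoff}): {self.n_top}",
            f"best model: "
            f"{'+'.join(best.terms) if best.terms else '(intercept)'}"
            f"   AICc={best.aicc:.2f}",
            f"sigma_country={best.sigma_country:.3f}  "
            f"sigma_resid={best.sigma_resid:.3f}"
            + ("  [singular: random intercept at 0]" if best.fit.singular else ""),
            "",
            "conditionally averaged coefficients:",
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def selection_table(self) -> pd.DataFrame:
        return self.model_set.to_frame()
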