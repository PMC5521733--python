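"""Leave-one-out cross-validation and direct-benefit-transfer baselines.

Each record is dropped in turn, the full selection-and-averaging procedure
is re-run on the remainder, and the held-out record is predicted.  Accuracy
is summarized by the mean absolute percentage error (MAPE, computed on the
log-value scale — the model's response — with a back-transformed option)
and by the slope of the predicted-versus-observed regression forced through
the origin (observed regressed on predicted: ``slope = sum(pred*obs) /
sum(pred^2)``).

The direct-benefit-transfer (DBT) baseline predicts a held-out record by the
leave-one-out mean log value of its stratum: ES class alone at the global
level, ES class x region at the regional level; an empty stratum falls back
to the global leave-one-out mean with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import DEFAULT_CANDIDATE_TERMS
from .predict import average_predict
from .selection import enumerate_models, select_top

__all__ = ["CVProcedure", "CVResult", "loo_cv", "direct_benefit_transfer",
           "through_origin_slope"]


@dataclass
class CVProcedure:
    """The model-building procedure cross-validation must replay in full."""

    candidate_terms: tuple[str, ...] = DEFAULT_CANDIDATE_TERMS
    cutoff: float = 2.0

    def build(self, records: pd.DataFrame):
        return select_top(enumerate_models(records, self.candidate_terms),
                          cutoff=self.cutoff)


@dataclass
class CVResult:
    """Held-out predictions and their accuracy summaries."""

    predictions: pd.DataFrame   # columns: observed, predicted (log scale)
    mape: float                 # on the log-value scale
    mape_backtransformed: float
    slope: float                # through-origin, observed ~ predicted
    r2: float                   # through-origin R^2
    n_fallback: int = 0         # records predicted without a stratum/country

    def summary(self) -> str:
        return (f"LOO-CV over n={len(self.predictions)} records: "
                f"MAPE(log)={self.mape:.4f}, slope={self.slope:.4f}, "
                f"R2={self.r2:.4f}")


def through_origin_slope(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """Through-origin regression of observed on predicted: (slope, R^2)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    denom = float(pred @ pred)
    slope = float(pred @ obs) / denom if denom > 0 else np.nan
    ss_res = float(np.sum((obs - slope * pred) ** 2))
    ss_tot = float(obs @ obs)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return slope, r2


def _mape(pred: np.ndarray, obs: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float)
    return float(np.mean(np.abs(pred - obs) / np.abs(obs)))


def _summarize(observed: np.ndarray, predicted: np.ndarray,
               n_fallback: int) -> CVResult:
    slope, r2 = through_origin_slope(predicted, observed)
    return CVResult(
        predictions=pd.DataFrame({"observed": observed, "predicted": predicted}),
        mape=_mape(predicted, observed),
        mape_backtransformed=_mape(np.exp(predicted), np.exp(observed)),
        slope=slope,
        r2=r2,
        n_fallback=n_fallback,
    )


def loo_cv(records: pd.DataFrame,
           procedure: CVProcedure | None = None) -> CVResult:
    """Leave-one-out CV replaying enumeration + selection + averaging."""
    if len(records) < 3:
        raise ValueError("leave-one-out CV needs at least 3 records")
    procedure = procedure or CVProcedure()
    records = records.reset_index(drop=True)
    observed = records["log_value"].to_numpy()
    predicted = np.empty(len(records))
    n_fallback = 0
    for i in range(len(records)):
        training = records.drop(index=i)
        top = procedure.build(training)
        held_out = records.iloc[[i]]
        if held_out["country"].iloc[0] not in set(training["country"]):
            n_fallback += 1  # fixed-effects-only path
        predicted[i] = average_predict(top, held_out)[0]
    return _summarize(observed, predicted, n_fallback)


def direct_benefit_transfer(records: pd.DataFrame,
                            level: str = "global") -> CVResult:
    """Leave-one-out stratum-mean baseline (global or regional)."""
    if level not in ("global", "regional"):
        raise ValueError(f"unknown DBT level {level!r}")
    if level == "regional" and "region" not in records.columns:
        raise ValueError("regional DBT requires a 'region' column per record")
    records = records.reset_index(drop=True)
    observed = records["log_value"].to_numpy()
    total = observed.sum()
    n = len(records)
    predicted = np.empty(n)
    n_fallback = 0
    strata = (records["es_class"] if level == "global"
              else records["es_class"] + "|" + records["region"])
    strata = strata.to_numpy()
    for i in range(n):
        mask = (strata == strata[i])
        mask[i] = False
        if mask.sum() == 0:
            predicted[i] = (total - observed[i]) / (n - 1)  # global LOO mean
            n_fallback += 1
        else:
            predicted[i] = observed[mask].mean()
    return _summarize(observed, predicted, n_fallback)
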