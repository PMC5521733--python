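"""Model fitting, AICc-based enumeration, selection and Akaike weights.

Every candidate model shares the random-intercept structure (country) and
differs only in its fixed-effect term subset.  All ``2^J`` subsets of the
candidate terms — the intercept-only model included — are fitted by ML,
ranked by AICc, and the models within the cutoff (default 2 AICc units of
the best) form the high-support set whose renormalized Akaike weights drive
model-averaged prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ..config import DEFAULT_CANDIDATE_TERMS
from ..design import DesignMatrixBuilder
from ..exceptions import ConfigurationError, FitError
from .lmm import LMMFit, fit_random_intercept

__all__ = ["FittedModel", "ModelSet", "aicc", "akaike_weights",
           "fit_mixed_model", "enumerate_models", "select_top"]


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    ``AICc = -2 ll + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``.
    """
    if n <= k + 1:
        raise ConfigurationError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(delta_aicc, weights) over a model set; weights sum to 1."""
    aicc_values = np.asarray(aicc_values, dtype=float)
    delta = aicc_values - aicc_values.min()
    raw = np.exp(-delta / 2.0)
    return delta, raw / raw.sum()


@dataclass
class FittedModel:
    """One ML-fitted mixed model: term subset plus all estimates."""

    terms: tuple[str, ...]
    fit: LMMFit
    aicc: float

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def k(self) -> int:
        return self.fit.k

    @property
    def n(self) -> int:
        return self.fit.n

    @property
    def columns(self) -> tuple[str, ...]:
        return self.fit.columns

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.fit.columns, self.fit.beta))

    @property
    def sigma_country(self) -> float:
        return self.fit.sigma_country

    @property
    def sigma_resid(self) -> float:
        return self.fit.sigma_resid

    @property
    def country_effects(self) -> dict[int, float]:
        return self.fit.group_effects


def _encode_groups(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(records["country"].to_numpy(), return_inverse=True)
    return codes, labels


def fit_mixed_model(records: pd.DataFrame, terms: tuple[str, ...],
                    builder: DesignMatrixBuilder | None = None) -> FittedModel:
    """Fit one term subset by ML and attach its AICc."""
    terms = tuple(terms)
    if builder is None:
        builder = DesignMatrixBuilder(terms).fit(records)
    X, cols = builder.transform(records, terms=terms)
    codes, labels = _encode_groups(records)
    fit = fit_random_intercept(records["log_value"].to_numpy(), X, codes,
                               columns=cols, group_labels=labels)
    return FittedModel(terms=terms, fit=fit, aicc=aicc(fit.loglik, fit.k, fit.n))


@dataclass
class ModelSet:
    """An enumerated (or refitted) collection of candidate models."""

    models: list[FittedModel]
    builder: DesignMatrixBuilder
    delta_aicc: np.ndarray = field(default=None)
    akaike_weight: np.ndarray = field(default=None)
    top_mask: np.ndarray | None = None
    cutoff: float | None = None
    failed: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.delta_aicc is None:
            self.recompute_weights()

    def recompute_weights(self) -> None:
        values = np.array([m.aicc for m in self.models])
        self.delta_aicc, self.akaike_weight = akaike_weights(values)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def best(self) -> FittedModel:
        return self.models[int(np.argmin(self.delta_aicc))]

    @property
    def top_models(self) -> list[FittedModel]:
        if self.top_mask is None:
            return list(self.models)
        return [m for m, keep in zip(self.models, self.top_mask) if keep]

    @property
    def top_weights(self) -> np.ndarray:
        """Akaike weights of the retained models, renormalized to sum to 1."""
        if self.top_mask is None:
            w = self.akaike_weight
        else:
            w = self.akaike_weight[self.top_mask]
        return w / w.sum()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.models):
            rows.append({
                "terms": "+".join(m.terms) if m.terms else "(intercept)",
                "k": m.k, "loglik": m.loglik, "aicc": m.aicc,
                "delta_aicc": self.delta_aicc[i],
                "weight": self.akaike_weight[i],
                "top": bool(self.top_mask[i]) if self.top_mask is not None else None,
            })
        return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)


def enumerate_models(records: pd.DataFrame,
                     candidate_terms: tuple[str, ...] = DEFAULT_CANDIDATE_TERMS,
                     builder: DesignMatrixBuilder | None = None) -> ModelSet:
    """Fit all ``2^J`` subsets of the candidate terms (intercept-only included)."""
    candidate_terms = tuple(candidate_terms)
    if len(candidate_terms) > 12:
        raise ConfigurationError(
            f"{len(candidate_terms)} candidate terms exceed the full-enumeration "
            "limit of 12 (4096 models)")
    if builder is None:
        builder = DesignMatrixBuilder(candidate_terms).fit(records)
    models: list[FittedModel] = []
    failed: list[tuple[tuple[str, ...], str]] = []
    for size in range(len(candidate_terms) + 1):
        for subset in combinations(candidate_terms, size):
            try:
                models.append(fit_mixed_model(records, subset, builder=builder))
            except FitError as exc:
                failed.append((subset, str(exc)))
    if not models:
        raise FitError("no candidate model could be fitted")
    return ModelSet(models=models, builder=builder, failed=failed)


def select_top(model_set: ModelSet, cutoff: float = 2.0) -> ModelSet:
    """Mark the high-support models (delta AICc <= cutoff, boundary inclusive)."""
    mask = model_set.delta_aicc <= cutoff
    return ModelSet(models=model_set.models, builder=model_set.builder,
                    delta_aicc=model_set.delta_aicc,
                    akaike_weight=model_set.akaike_weight,
                    top_mask=mask, cutoff=cutoff, failed=model_set.failed)
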