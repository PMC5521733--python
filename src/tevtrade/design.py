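"""Design-matrix construction for the ES-value meta-analytic model.

Terms are named predictors.  The two clustered factors expand to treatment
dummies — ES class against the ``cultural`` baseline, valuation method
against the ``cost_based`` baseline — and continuous predictors are z-scored
against the training sample, so coefficients are per-standard-deviation
effects.  The same builder is used by the synthetic generator (so the
generative truth lives on exactly the scale the model estimates) and by
prediction, where the stored training moments are reused and the two
predictors without spatial counterparts (publication year, forest area) are
fixed at their training means when absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FitError

ES_LEVELS = ("cultural", "provisioning", "regulating")
METHOD_LEVELS = ("cost_based", "revealed", "stated")

#: predictors allowed to be absent at prediction time (fixed at training mean)
MEAN_FILLABLE = ("year", "forest_area")

#: binary predictors kept on their natural 0/1 scale
BINARY_TERMS = ("peer_reviewed", "protected_area")


def term_columns(term: str) -> tuple[str, ...]:
    """Design column names a term expands to."""
    if term == "es_class":
        return tuple(f"es_class[{lvl}]" for lvl in ES_LEVELS[1:])
    if term == "method_class":
        return tuple(f"method_class[{lvl}]" for lvl in METHOD_LEVELS[1:])
    return (term,)


def _raw_column(records: pd.DataFrame, col: str) -> np.ndarray:
    if col.startswith("es_class["):
        level = col[len("es_class["):-1]
        _check_levels(records["es_class"], ES_LEVELS, "es_class")
        return (records["es_class"].to_numpy() == level).astype(float)
    if col.startswith("method_class["):
        level = col[len("method_class["):-1]
        _check_levels(records["method_class"], METHOD_LEVELS, "method_class")
        return (records["method_class"].to_numpy() == level).astype(float)
    if col not in records.columns:
        raise KeyError(f"missing covariate {col!r} in prediction data")
    values = records[col].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ConfigurationError(f"covariate {col!r} contains missing values")
    return values


def _check_levels(series: pd.Series, levels: tuple[str, ...], name: str) -> None:
    bad = set(series.unique()) - set(levels)
    if bad:
        raise ConfigurationError(f"{name} contains unknown levels {sorted(bad)}")


@dataclass
class DesignMatrixBuilder:
    """Builds (and remembers the scaling of) the fixed-effects design."""

    terms: tuple[str, ...]
    standardize: bool = True
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)

    @property
    def columns(self) -> tuple[str, ...]:
        return ("intercept",) + tuple(
            c for t in self.terms for c in term_columns(t))

    def _is_scaled(self, col: str) -> bool:
        return (self.standardize and "[" not in col
                and col not in BINARY_TERMS and col != "intercept")

    def fit(self, records: pd.DataFrame) -> "DesignMatrixBuilder":
        """Record training means/sds of the continuous columns."""
        for col in self.columns:
            if not self._is_scaled(col):
                continue
            values = _raw_column(records, col)
            sd = float(np.std(values))
            self.means[col] = float(np.mean(values))
            self.sds[col] = sd if sd > 0 else 1.0
        self.fitted = True
        return self

    def transform(self, records: pd.DataFrame, terms: tuple[str, ...] | None = None,
                  allow_mean_fill: bool = False) -> tuple[np.ndarray, tuple[str, ...]]:
        """Design matrix for a (sub)set of the fitted terms.

        With ``allow_mean_fill`` the mean-fillable predictors (publication
        year, forest area) may be absent from ``records`` and enter at their
        training mean, i.e. a standardized value of zero.
        """
        if not self.fitted:
            raise FitError("builder must be fit() before transform()")
        if terms is None:
            terms = self.terms
        unknown = set(terms) - set(self.terms)
        if unknown:
            raise ConfigurationError(f"terms {sorted(unknown)} were not fitted")
        n = len(records)
        cols = ["intercept"] + [c for t in terms for c in term_columns(t)]
        out = np.empty((n, len(cols)))
        for j, col in enumerate(cols):
            if col == "intercept":
                out[:, j] = 1.0
                continue
            if (allow_mean_fill and col in MEAN_FILLABLE
                    and col not in records.columns):
                out[:, j] = 0.0
                continue
            values = _raw_column(records, col)
            if self._is_scaled(col):
                values = (values - self.means[col]) / self.sds[col]
            out[:, j] = values
        return out, tuple(cols)

    def fit_transform(self, records: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
        return self.fit(records).transform(records)


def terms_from_beta(true_beta: dict[str, float]) -> tuple[str, ...]:
    """Infer the term list underlying a coefficient dictionary."""
    terms: list[str] = []
    for key in true_beta:
        if key == "intercept":
            continue
        term = key.split("[")[0]
        if term not in terms:
            terms.append(term)
    return tuple(terms)


def beta_vector(true_beta: dict[str, float], columns: tuple[str, ...]) -> np.ndarray:
    """Order a coefficient dict along design columns (absent -> 0)."""
    return np.array([float(true_beta.get(c, 0.0)) for c in columns])
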