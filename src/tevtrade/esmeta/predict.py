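"""Model-averaged prediction and spatial TEV mapping.

Predictions from the high-support models are combined as a weighted average
with renormalized Akaike weights.  Conditional prediction adds the estimated
country intercept where the country was observed in training; countries
without an estimable random effect are predicted with the fixed-effects part
only.  Publication year and forest area, which have no spatial counterpart,
enter at their training means when absent from the prediction data.

Per-cell total ES value (TEV) follows the aggregation convention of the
meta-analysis: one log-scale prediction per valuation-method level, averaged
over the three levels, back-transformed, then combined across ES classes
with the class multipliers (default 5 provisioning, 6 regulating after
excluding the carbon-overlapping service, 5 cultural).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import DEFAULT_MULTIPLIERS, validate_multipliers
from ..design import METHOD_LEVELS
from ..grid import LandscapeGrid
from ..synthgen import grid_newdata
from .selection import FittedModel, ModelSet

__all__ = ["predict_single", "average_predict", "predict_tev_grid"]


def predict_single(model: FittedModel, model_set: ModelSet,
                   newdata: pd.DataFrame, conditional: bool = True) -> np.ndarray:
    """Log-scale prediction from one fitted model."""
    X, _ = model_set.builder.transform(newdata, terms=model.terms,
                                       allow_mean_fill=True)
    pred = X @ model.fit.beta
    if conditional and "country" in newdata.columns:
        effects = model.country_effects
        pred = pred + np.array([effects.get(int(c), 0.0)
                                for c in newdata["country"]])
    return pred


def average_predict(top_set: ModelSet, newdata: pd.DataFrame,
                    mode: str = "conditional") -> np.ndarray:
    """Akaike-weighted average of the retained models' log predictions."""
    conditional = mode == "conditional"
    weights = top_set.top_weights
    preds = np.stack([predict_single(m, top_set, newdata, conditional)
                      for m in top_set.top_models])
    return weights @ preds


def predict_tev_grid(top_set: ModelSet, grid: LandscapeGrid,
                     multipliers: dict[str, float] | None = None,
                     mode: str = "conditional",
                     ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-cell TEV surface (currency/ha/yr) and per-ES-class components.

    Returns ``(tev, components)`` where ``tev`` is a (ny, nx) array and
    ``components`` maps each ES class to its per-cell back-transformed value
    before multiplication.
    """
    multipliers = validate_multipliers(multipliers or DEFAULT_MULTIPLIERS)
    newdata = grid_newdata(grid)
    tev = np.zeros(grid.n_cells)
    components: dict[str, np.ndarray] = {}
    for es_class, mult in multipliers.items():
        log_preds = [
            average_predict(
                top_set,
                newdata.assign(es_class=es_class, method_class=method),
                mode=mode)
            for method in METHOD_LEVELS
        ]
        value = np.exp(np.mean(log_preds, axis=0))
        components[es_class] = value.reshape(grid.shape)
        tev += mult * value
    return tev.reshape(grid.shape), components
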