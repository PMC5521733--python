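"""Bootstrap uncertainty for the spatial ES-value predictions.

The record table is resampled with replacement B times (rows by default;
study-level cluster resampling via ``cluster_col``).  Each replicate refits
the already-selected high-support model structures, recomputes their AICc
weights, and re-predicts the TEV surface — re-running the full 2^J
enumeration per replicate is available behind ``reenumerate=True``.
Replicates whose design becomes rank-deficient (e.g. a factor level vanishes
from the resample) are redrawn and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._rng import stream
from ..config import DEFAULT_CANDIDATE_TERMS, DEFAULT_MULTIPLIERS, validate_multipliers
from ..exceptions import FitError
from ..grid import LandscapeGrid
from .predict import predict_tev_grid
from .selection import ModelSet, enumerate_models, fit_mixed_model, select_top

__all__ = ["ESMapEnsemble", "bootstrap_es_maps"]

_MAX_REDRAWS = 200


@dataclass
class ESMapEnsemble:
    """B bootstrap TEV surfaces plus the full-sample point estimate."""

    maps: np.ndarray                      # (B, ny, nx), currency/ha/yr
    component_maps: dict[str, np.ndarray]  # es_class -> (B, ny, nx)
    point_map: np.ndarray                 # (ny, nx)
    point_components: dict[str, np.ndarray]
    n_redrawn: int = 0

    @property
    def B(self) -> int:
        return self.maps.shape[0]

    def percentile_maps(self, probs=(2.5, 50.0, 97.5)) -> dict[float, np.ndarray]:
        return {p: np.percentile(self.maps, p, axis=0) for p in probs}

    def mean_map(self) -> np.ndarray:
        return self.maps.mean(axis=0)


def _refit_top(training: pd.DataFrame, top: ModelSet) -> ModelSet:
    """Refit the retained structures on a resample; recompute weights.

    The covariate standardization (and the year/forest-area mean-fill
    values) are fixed preprocessing from the original fit, so replicates
    re-estimate coefficients on an identical design scale.
    """
    models = [fit_mixed_model(training, m.terms, builder=top.builder)
              for m in top.top_models]
    return ModelSet(models=models, builder=top.builder)


def bootstrap_es_maps(records: pd.DataFrame, grid: LandscapeGrid,
                      B: int = 500, seed: int = 0,
                      candidate_terms: tuple[str, ...] = DEFAULT_CANDIDATE_TERMS,
                      cutoff: float = 2.0,
                      multipliers: dict[str, float] | None = None,
                      reenumerate: bool = False,
                      cluster_col: str | None = None,
                      force_full_sample: bool = False,
                      top_set: ModelSet | None = None) -> ESMapEnsemble:
    """Seeded bootstrap ensemble of per-cell TEV surfaces.

    ``force_full_sample`` replaces every resample by the full dataset (a
    degenerate bootstrap useful for consistency checks), and ``top_set``
    lets a caller reuse an already-enumerated selection.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    multipliers = validate_multipliers(multipliers or DEFAULT_MULTIPLIERS)
    records = records.reset_index(drop=True)
    if top_set is None:
        top_set = select_top(enumerate_models(records, candidate_terms), cutoff)
    point_map, point_components = predict_tev_grid(top_set, grid, multipliers)

    rng = stream(seed, "es_bootstrap")
    n = len(records)
    maps = np.empty((B,) + grid.shape)
    component_maps = {cls: np.empty((B,) + grid.shape) for cls in multipliers}
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(_MAX_REDRAWS):
            if force_full_sample:
                sample = records
            elif cluster_col is not None:
                clusters = records[cluster_col].unique()
                chosen = rng.choice(clusters, size=len(clusters), replace=True)
                sample = pd.concat(
                    [records[records[cluster_col] == c] for c in chosen],
                    ignore_index=True)
            else:
                sample = records.iloc[rng.integers(0, n, size=n)].reset_index(drop=True)
            try:
                if reenumerate:
                    rep_set = select_top(
                        enumerate_models(sample, candidate_terms), cutoff)
                else:
                    rep_set = _refit_top(sample, top_set)
                tev, comps = predict_tev_grid(rep_set, grid, multipliers)
                break
            except FitError:
                if force_full_sample:
                    raise
                n_redrawn += 1
        else:
            raise FitError(f"bootstrap replicate {b} failed {_MAX_REDRAWS} redraws")
        maps[b] = tev
        for cls in multipliers:
            component_maps[cls][b] = comps[cls]
    return ESMapEnsemble(maps=maps, component_maps=component_maps,
                         point_map=point_map, point_components=point_components,
                         n_redrawn=n_redrawn)
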