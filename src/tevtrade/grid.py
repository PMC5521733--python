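"""The gridded landscape: per-cell biophysical and economic state.

A :class:`LandscapeGrid` wraps an :class:`xarray.Dataset` with dims
``(y, x)`` — row-major from the north-west corner, ``cell_id = row * nx +
col`` — holding one data variable per layer.  Per-crop layers are named
``yield_<crop>`` and ``potential_yield_<crop>``.  Grid-level metadata (cell
area, crop set, per-country crop composition and region labels) travels in
``attrs`` and sidecar tables.

On disk the grid is a long-format CSV (``cell_id,layer,value``, UTF-8,
comma) plus a small JSON sidecar for the metadata, so the package needs no
geospatial binary dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import ConfigurationError, GeometryError

#: layers every grid must carry (beyond per-crop yield layers)
MANDATORY_LAYERS = (
    "country_id", "forest_loss_area", "agb_carbon", "bgb_carbon",
    "dom_carbon", "peat_depth", "pasture_fraction", "cattle_stocking",
    "travel_time", "fertilizer_usage", "growing_stock",
    "temperature", "precipitation", "accessibility", "population",
    "altitude", "gdp", "protected_area", "richness_birds",
    "richness_amphibians", "richness_mammals", "richness_plants",
    "carbon_density",
)


@dataclass
class LandscapeGrid:
    """Container for per-cell rasters of a synthetic (or real) landscape."""

    data: xr.Dataset
    cell_area: float
    crops: tuple[str, ...]
    crop_composition: pd.DataFrame = field(repr=False)  # index country, cols crops+cattle
    country_region: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.crops = tuple(self.crops)
        self.validate()

    # -- geometry ---------------------------------------------------------
    @property
    def ny(self) -> int:
        return self.data.sizes["y"]

    @property
    def nx(self) -> int:
        return self.data.sizes["x"]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.ny * self.nx

    def cell_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (y, x) centre coordinates in cell units, row-major."""
        yy, xx = np.meshgrid(np.arange(self.ny), np.arange(self.nx), indexing="ij")
        return yy.ravel() + 0.5, xx.ravel() + 0.5

    # -- layer access -----------------------------------------------------
    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(self.data.data_vars)

    def layer(self, name: str) -> np.ndarray:
        """2-D (ny, nx) array for a named layer."""
        if name not in self.data:
            raise KeyError(f"grid has no layer {name!r}")
        return self.data[name].values

    def flat(self, name: str) -> np.ndarray:
        """Row-major flattened layer (length n_cells)."""
        return self.layer(name).ravel()

    @property
    def countries(self) -> np.ndarray:
        return np.unique(self.layer("country_id").astype(int))

    def with_layer(self, name: str, values: np.ndarray) -> "LandscapeGrid":
        """Return a copy with one layer replaced."""
        values = np.asarray(values, dtype=float).reshape(self.shape)
        data = self.data.copy()
        data[name] = (("y", "x"), values)
        return LandscapeGrid(data, self.cell_area, self.crops,
                             self.crop_composition.copy(), dict(self.country_region))

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        missing = [l for l in MANDATORY_LAYERS if l not in self.data]
        for crop in self.crops:
            for prefix in ("yield_", "potential_yield_"):
                if prefix + crop not in self.data:
                    missing.append(prefix + crop)
        if missing:
            raise ConfigurationError(f"grid is missing mandatory layers: {missing}")
        if self.cell_area <= 0:
            raise ConfigurationError("cell_area must be > 0")
        loss = self.layer("forest_loss_area")
        if np.any(loss < 0) or np.any(loss > self.cell_area + 1e-9):
            raise ConfigurationError("forest_loss_area must lie in [0, cell_area]")
        for name in ("agb_carbon", "bgb_carbon", "dom_carbon", "peat_depth"):
            if np.any(self.layer(name) < 0):
                raise ConfigurationError(f"layer {name!r} must be non-negative")

    def assert_same_geometry(self, arr: np.ndarray, what: str = "array") -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.shape:
            raise GeometryError(f"{what} shape {arr.shape} != grid shape {self.shape}")
        return arr

    # -- conversion / IO --------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (cell_id, layer, value) table, layers in stored order."""
        ids = np.arange(self.n_cells)
        parts = [
            pd.DataFrame({"cell_id": ids, "layer": name, "value": self.flat(name)})
            for name in self.layers
        ]
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_long_frame().to_csv(path, index=False)
        meta = {
            "ny": self.ny,
            "nx": self.nx,
            "cell_area": self.cell_area,
            "crops": list(self.crops),
            "crop_composition": {
                str(k): dict(v) for k, v in self.crop_composition.iterrows()
            },
            "country_region": {str(k): v for k, v in self.country_region.items()},
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path) -> "LandscapeGrid":
        path = Path(path)
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # pandas names the offending row/byte
            raise ConfigurationError(f"cannot parse grid CSV {path}: {exc}") from exc
        expected = {"cell_id", "layer", "value"}
        if set(frame.columns) != expected:
            raise ConfigurationError(
                f"grid CSV must have columns {sorted(expected)}, got {list(frame.columns)}")
        meta_path = Path(str(path) + ".meta.json")
        if not meta_path.exists():
            raise ConfigurationError(f"missing grid metadata sidecar {meta_path}")
        meta = json.loads(meta_path.read_text())
        ny, nx = int(meta["ny"]), int(meta["nx"])
        n_cells = ny * nx
        data = {}
        for name, sub in frame.groupby("layer", sort=False):
            sub = sub.sort_values("cell_id")
            if len(sub) != n_cells:
                raise ConfigurationError(
                    f"layer {name!r} has {len(sub)} cells, expected {n_cells}")
            data[name] = (("y", "x"), sub["value"].to_numpy().reshape(ny, nx))
        comp = pd.DataFrame.from_dict(meta["crop_composition"], orient="index")
        comp.index = comp.index.astype(int)
        comp.index.name = "country_id"
        return cls(
            xr.Dataset(data),
            cell_area=float(meta["cell_area"]),
            crops=tuple(meta["crops"]),
            crop_composition=comp,
            country_region={int(k): v for k, v in meta["country_region"].items()},
        )
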