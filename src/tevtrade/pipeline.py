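"""End-to-end pipeline: inputs -> meta-analysis -> rents -> impacts -> MC.

``run_pipeline`` executes the full chain — screen records, enumerate/select/
average the ES models, bootstrap the TEV surfaces, value carbon, compute
scenario rents, integrate impacts, propagate uncertainty, reduce to
percentiles — and writes every artifact as CSV/JSON under the output
directory together with a manifest of seeds, component versions and
per-file SHA-256 checksums.  Re-running the same configuration reproduces
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agrorent import rent_map
from .carbonval import (DEFAULT_PEAT_C_PER_M, CarbonPools, annualize,
                        cell_emissions, price_emissions)
from .config import (DEFAULT_CANDIDATE_TERMS, DEFAULT_MULTIPLIERS,
                     CarbonPriceModel, ScenarioSpec, SynthConfig,
                     UncertaintySpec, validate_multipliers)
from .econ import EconTables
from .esmeta import ESValueModel, screen_records
from .exceptions import ConfigurationError
from .grid import LandscapeGrid
from .mcengine import MonteCarloEngine, reduce_percentiles
from .synthgen import (generate_econ_tables, generate_landscape,
                       generate_valuation_dataset)
from .tradeoff import internalization_map

log = logging.getLogger("tevtrade")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    output_dir: str = "tevtrade_out"
    seed: int = 0
    scenarios: tuple[str, ...] = ("A", "B", "C", "D")
    synth: SynthConfig | None = None          # generate inputs ...
    grid_path: str | None = None              # ... or load them
    records_path: str | None = None
    econ_path: str | None = None
    candidate_terms: tuple[str, ...] = DEFAULT_CANDIDATE_TERMS
    cutoff: float = 2.0
    multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    bootstrap_B: int = 500
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    carbon: CarbonPriceModel = field(default_factory=CarbonPriceModel)
    peat_c_per_m: float = DEFAULT_PEAT_C_PER_M
    impact_mode: str = "tev_market"

    def __post_init__(self) -> None:
        self.scenarios = tuple(str(s).upper() for s in self.scenarios)
        for s in self.scenarios:
            ScenarioSpec.from_id(s)  # validates before any compute
        self.multipliers = validate_multipliers(self.multipliers)
        if self.synth is None and self.grid_path is None:
            raise ConfigurationError("either synth config or input paths required")
        for path_attr in ("grid_path", "records_path", "econ_path"):
            path = getattr(self, path_attr)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{path_attr} {path!r} does not exist")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "uncertainty" in raw and isinstance(raw["uncertainty"], dict):
            raw["uncertainty"] = UncertaintySpec(**raw["uncertainty"])
        if "carbon" in raw and isinstance(raw["carbon"], dict):
            raw["carbon"] = CarbonPriceModel(**raw["carbon"])
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        if "candidate_terms" in raw:
            raw["candidate_terms"] = tuple(raw["candidate_terms"])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw = (json.loads(text) if path.suffix == ".json"
               else yaml.safe_load(text))
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_cell_csv(path: Path, arr: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": np.arange(arr.size),
                  "value": arr.ravel()}).to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run every stage and return the output manifest."""
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigurationError(
            f"output directory {out} is not empty; pass force=True (--force)")
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_frame(frame: pd.DataFrame, rel: str, index: bool = False) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=index)
        written.append(path)

    # -- stage 1: inputs --------------------------------------------------
    if config.synth is not None:
        log.info("stage simulate: generating synthetic inputs")
        grid = generate_landscape(config.synth)
        records, _truth = generate_valuation_dataset(config.synth, grid)
        econ = generate_econ_tables(config.synth)
        grid.write_csv(out / "inputs" / "grid.csv")
        written += [out / "inputs" / "grid.csv",
                    out / "inputs" / "grid.csv.meta.json"]
        save_frame(records, "inputs/records.csv")
        econ.write_dir(out / "inputs" / "econ")
        written += sorted((out / "inputs" / "econ").iterdir())
    else:
        log.info("stage load: reading inputs")
        grid = LandscapeGrid.read_csv(config.grid_path)
        records = pd.read_csv(config.records_path)
        econ = EconTables.read_dir(config.econ_path)

    # -- stage 2: screening ----------------------------------------------
    records, screening_report = screen_records(records)
    log.info("stage screen: %s", screening_report.summary().splitlines()[0])

    # -- stage 3: meta-analysis ------------------------------------------
    log.info("stage fit-es: enumerating %d models",
             2 ** len(config.candidate_terms))
    results = ESValueModel(records, config.candidate_terms,
                           config.cutoff).fit()
    save_frame(results.selection_table().head(50), "es/selection_table.csv")
    save_frame(results.params, "es/averaged_coefficients.csv", index=True)

    # -- stage 4: bootstrap ES maps --------------------------------------
    log.info("stage bootstrap: B=%d TEV surfaces", config.bootstrap_B)
    ensemble = results.bootstrap_maps(grid, B=config.bootstrap_B,
                                      seed=config.seed,
                                      multipliers=config.multipliers)
    _write_cell_csv(out / "es" / "tev_point.csv", ensemble.point_map)
    written.append(out / "es" / "tev_point.csv")

    # -- stage 5: carbon --------------------------------------------------
    pools = CarbonPools(agb_c=grid.layer("agb_carbon"),
                        bgb_c=grid.layer("bgb_carbon"),
                        dom_c=grid.layer("dom_carbon"),
                        peat_depth=grid.layer("peat_depth"),
                        peat_c_per_m=config.peat_c_per_m)
    emissions = cell_emissions(pools)
    market_mean = float(econ.carbon_market["price"].mean())
    carbon_annual = annualize(
        price_emissions(emissions, market_mean, config.carbon.price_basis),
        config.carbon.discount_rate, config.carbon.horizon)
    _write_cell_csv(out / "carbon" / "emissions_tco2e_ha.csv", emissions)
    _write_cell_csv(out / "carbon" / "value_market_annual.csv", carbon_annual)
    written += [out / "carbon" / "emissions_tco2e_ha.csv",
                out / "carbon" / "value_market_annual.csv"]

    # -- stage 6: scenarios, impacts, Monte Carlo ------------------------
    intern = internalization_map(econ, grid)
    _write_cell_csv(out / "internalization.csv", intern)
    written.append(out / "internalization.csv")
    for scenario_id in config.scenarios:
        scenario = ScenarioSpec.from_id(scenario_id)
        log.info("stage scenario %s: rents + Monte Carlo (M=%d)",
                 scenario_id, config.uncertainty.n_reps)
        sdir = f"scenario_{scenario_id}"
        ar, assignment = rent_map(grid, scenario, econ, rng=config.seed,
                                  r=config.carbon.discount_rate,
                                  T=config.carbon.horizon)
        _write_cell_csv(out / sdir / "rent_point.csv", ar)
        _write_cell_csv(out / sdir / "crop_assignment.csv",
                        assignment.astype(float))
        written += [out / sdir / "rent_point.csv",
                    out / sdir / "crop_assignment.csv"]

        uspec = UncertaintySpec(
            n_reps=config.uncertainty.n_reps,
            loss_accuracy=config.uncertainty.loss_accuracy,
            noloss_accuracy=config.uncertainty.noloss_accuracy,
            sources=dict(config.uncertainty.sources),
            seed=config.seed)
        engine = MonteCarloEngine(grid, ensemble, econ, scenario, uspec,
                                  carbon_model=config.carbon,
                                  multipliers=config.multipliers,
                                  peat_c_per_m=config.peat_c_per_m,
                                  impact_mode=config.impact_mode)
        outcome = engine.run()
        save_frame(outcome.aggregates, f"{sdir}/aggregates.csv")
        save_frame(outcome.country_aggregates, f"{sdir}/country_aggregates.csv")
        reduced = reduce_percentiles(outcome)
        save_frame(reduced["table"], f"{sdir}/percentile_table.csv", index=True)
        for p, arr in reduced["maps"].items():
            _write_cell_csv(out / sdir / f"impact_p{p}.csv", arr)
            written.append(out / sdir / f"impact_p{p}.csv")

    # -- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "scenarios": list(config.scenarios),
        "bootstrap_B": config.bootstrap_B,
        "mc_reps": config.uncertainty.n_reps,
        "screening": screening_report.removed,
        "n_records": len(records),
        "n_top_models": results.n_top,
        "checksums": {str(p.relative_to(out)): _sha256(p)
                      for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete: %d artifacts in %s",
             len(manifest["checksums"]), out)
    return manifest
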