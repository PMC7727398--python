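"""End-to-end orchestration of the price-analysis stages.

A single :class:`RunConfig` drives: simulate -> normalize -> calendar ->
annual -> seasonal -> predict -> summarize.  Every stage is a pure function
of (inputs, config, seed); the run report collects counts, fitted
parameters, and model evaluations, and the resolved configuration is written
next to the outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annual as annual_mod
from . import cropcal, seasonal, spatial, summary
from .panel import PricePanel, build_panel
from .synthetic import SyntheticConfig, SyntheticDataset, simulate

__all__ = ["RunConfig", "run_all", "report_hash"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "calendar", "annual", "seasonal", "predict", "summarize")
_DEPENDS = {
    "normalize": ("simulate",),
    "calendar": ("simulate",),
    "annual": ("normalize", "calendar"),
    "seasonal": ("normalize", "calendar"),
    "predict": ("normalize", "calendar", "seasonal"),
    "summarize": ("normalize",),
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults are the analysis constants: wetness threshold clamp 30-90 mm,
    arid cutoff 200 mm, at least 10 years for the annual analysis, a 50 km
    rainfall buffer, and 10 market-grouped cross-validation folds.
    """

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    arid_cutoff_mm: float = 200.0
    min_run_length: int = 1
    min_years: int = 10
    buffer_km: float = 50.0
    n_folds: int = 10
    n_trees: int = 500
    impute_maize: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        # one seed drives everything; the generator inherits it
        self.synthetic.seed = self.seed

    def as_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists for YAML comparability
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


class StageDependencyError(RuntimeError):
    pass


def _check_dependencies(stages: tuple[str, ...]) -> None:
    enabled = set(stages)
    for st in stages:
        missing = [d for d in _DEPENDS.get(st, ()) if d not in enabled]
        if missing:
            raise StageDependencyError(
                f"stage '{st}' requires disabled stage(s): {missing}"
            )


def _round(x, nd=10):
    return None if x is None or (isinstance(x, float) and not np.isfinite(x)) else round(float(x), nd)


def run_all(config: RunConfig | None = None) -> dict:
    """Execute the enabled stages in order and return the run report."""
    cfg = config or RunConfig()
    _check_dependencies(cfg.stages)
    report: dict = {"config": cfg.as_dict()}
    data: SyntheticDataset | None = None
    panel: PricePanel | None = None
    calendars = None
    indices = None

    if "simulate" in cfg.stages:
        data = simulate(cfg.synthetic)
        report["simulate"] = {
            "n_records": int(len(data.records)),
            "n_markets": int(len(data.markets)),
            "n_arid_markets": int(data.markets["arid_zone"].sum()),
            "years": [cfg.synthetic.year_start, cfg.synthetic.year_end],
        }

    if "normalize" in cfg.stages:
        panel = build_panel(data.records, data.deflators, impute_maize=cfg.impute_maize)
        report["normalize"] = {
            "n_prices": int(len(panel.prices)),
            "source_counts": panel.source_counts(),
            "wholesale_slopes": {
                c: _round(m.slope_) for c, m in panel.conversion_models.items()
            },
            "skipped_no_deflator": panel.log.get("skipped_no_deflator", 0),
        }

    if "calendar" in cfg.stages:
        calendars = cropcal.calendars_from_series(
            data.market_rain, min_run_length=cfg.min_run_length,
            arid_cutoff=cfg.arid_cutoff_mm,
        )
        report["calendar"] = {
            "n_markets": len(calendars),
            "n_arid": sum(c.is_arid for c in calendars.values()),
            "n_two_season": sum(c.n_seasons == 2 for c in calendars.values()),
            "harvest_months": {
                k: list(v.harvest_months) for k, v in sorted(calendars.items())
            },
        }

    if "annual" in cfg.stages:
        summaries = annual_mod.summarize_harvest_years(panel, calendars, data.market_rain)
        effects = annual_mod.rain_price_effects(
            summaries, annual_rain=data.truth.mean_annual_rain, min_years=cfg.min_years
        )
        sect = {
            "n_harvest_years": len(summaries),
            "n_effects": len(effects),
            "mean_slope": _round(np.mean([e.slope for e in effects])) if effects else None,
        }
        if len(effects) >= 5:
            countries = dict(zip(panel.markets["market_id"], panel.markets["country"]))
            meta, _ = annual_mod.effect_vs_aridity(effects, cluster=countries)
            sect["meta"] = {
                "intercept": _round(meta.intercept), "slope": _round(meta.slope),
                "r_squared": _round(meta.r_squared), "n": meta.n,
            }
        report["annual"] = sect

    if "seasonal" in cfg.stages:
        indices = seasonal.all_temporal_indices(panel)
        fit = seasonal.align_and_fit(indices, calendars)
        report["seasonal"] = {
            "n_indices": len(indices),
            **{k: (_round(v) if isinstance(v, float) else v) for k, v in fit.summary().items()},
        }

    if "predict" in cfg.stages:
        table = spatial.temporal_training_table(
            indices, panel, data.climatology, buffer_km=cfg.buffer_km
        )
        cal_ok = {m for m, c in calendars.items() if c.harvest_months}
        table = table[table["market_id"].isin(cal_ok)]
        tmodel = spatial.TemporalIndexForest(
            n_estimators=cfg.n_trees, random_state=cfg.seed, n_folds=cfg.n_folds
        ).fit_table(table)

        maize = panel.prices[panel.prices["crop"] == "maize"]
        med = maize.groupby("market_id")["value"].median().rename("price").reset_index()
        feat = med.merge(panel.markets, on="market_id").merge(
            data.markets[["market_id", "tt_small", "tt_mid", "tt_large"]], on="market_id"
        )
        feat["annual_prec"] = [
            data.truth.mean_annual_rain[m] for m in feat["market_id"]
        ]
        smodel = spatial.SpatialPriceForest(
            n_estimators=cfg.n_trees, random_state=cfg.seed, n_folds=cfg.n_folds
        ).fit_table(feat)

        t_surface = spatial.predict_temporal_surface(tmodel, data.covariates)
        s_surface = spatial.predict_spatial_surface(smodel, data.covariates)
        report["predict"] = {
            "temporal": {k: _round(v) if isinstance(v, float) else v
                         for k, v in tmodel.evaluation_.as_dict().items()},
            "temporal_oob_r2": _round(tmodel.oob_r2_),
            "spatial": {k: _round(v) if isinstance(v, float) else v
                        for k, v in smodel.evaluation_.as_dict().items()},
            "spatial_oob_r2": _round(smodel.oob_r2_),
            "surface_checksums": {
                "temporal_index": _array_checksum(t_surface["index"].values),
                "temporal_range": _array_checksum(t_surface["index_range"].values),
                "spatial_price": _array_checksum(s_surface["price"].values),
            },
        }
        report["_surfaces"] = {"temporal": t_surface, "spatial": s_surface}

    if "summarize" in cfg.stages:
        ranges = summary.country_ranges(panel, crop="maize")
        report["summarize"] = {
            "n_countries": len(ranges),
            "mean_annual_range": _round(np.mean([r.annual_range for r in ranges])),
            "mean_seasonal_range": _round(np.mean([r.seasonal_range for r in ranges])),
            "mean_spatial_range": _round(np.mean([r.spatial_range for r in ranges])),
        }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.as_dict(), fh, sort_keys=True)
        surfaces = report.pop("_surfaces", None)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        if panel is not None:
            panel.to_csv(out / "panel.csv")
        if surfaces is not None:
            surfaces["temporal"].to_netcdf(out / "temporal_surface.nc", engine="scipy")
            surfaces["spatial"].to_netcdf(out / "spatial_surface.nc", engine="scipy")
            report["_surfaces"] = surfaces
    return report


def _array_checksum(a: np.ndarray) -> str:
    b = np.ascontiguousarray(np.nan_to_num(a, nan=-9999.0), dtype="<f8").tobytes()
    return hashlib.sha256(b).hexdigest()


def report_hash(report: dict) -> str:
    """Stable digest of a run report (surfaces folded in via checksums)."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return hashlib.sha256(
        json.dumps(clean, sort_keys=True, default=str).encode()
    ).hexdigest()
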