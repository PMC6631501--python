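"""End-to-end orchestration: design → fit → ANOVA → optimize → ANN → compare.

A :class:`PipelineConfig` (usually read from a YAML file) names the
input run table and output directory and fixes every seed, so two runs
with the same configuration produce byte-identical structured reports
(timestamps are deliberately excluded from all outputs).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import load_factors, load_fixture
from .design import FactorSpec, DesignTable, build_ccrd
from .metrics import compare_models
from .mlp import SplitSpec, train_mlp
from .optimize import box_constrained_max, ridge_max
from .quadratic import ExperimentTable, anova, fit_quadratic
from .datasets import _experiment_from_frame

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "load_config", "read_runs"]

log = logging.getLogger("rsmann")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, with study defaults."""

    input_table: str | None = None          # None → packaged 27-run fixture
    validation_table: str | None = "fixture"  # "fixture", a path, or None
    output_dir: str = "rsmann_out"
    alpha: float = 2.0
    n_center: int = 3
    design_seed: int = 0
    hidden: int = 10
    restarts: int = 20
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    ann_seed: int = 0
    bounds: tuple[float, float] = (-2.0, 2.0)
    ridge_radii_max: float = 2.0
    ridge_radii_n: int = 20

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        cfg = cls(**d)
        if cfg.input_table is not None and not Path(cfg.input_table).exists():
            raise ConfigError(f"input_table not found: {cfg.input_table}")
        if cfg.validation_table not in (None, "fixture") and not Path(
            cfg.validation_table
        ).exists():
            raise ConfigError(f"validation_table not found: {cfg.validation_table}")
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ConfigError("configuration file must hold a mapping")
    if "split" in d:
        d["split"] = tuple(d["split"])
    if "bounds" in d:
        d["bounds"] = tuple(d["bounds"])
    return PipelineConfig.from_dict(d)


def read_runs(path, factors: list[FactorSpec] | None = None) -> ExperimentTable:
    """Read a delimited run table (factor actual columns + ``yield``)."""
    factors = factors or load_factors()
    df = pd.read_csv(path)
    missing = [c for c in [f.name for f in factors] + ["yield"] if c not in df.columns]
    if missing:
        raise ConfigError(f"run table {path}: missing columns {missing}")
    if "yield_sd" not in df.columns:
        df = df.assign(yield_sd=np.nan)
    if "run" not in df.columns:
        df = df.assign(run=np.arange(1, len(df) + 1))
    return _experiment_from_frame(df, factors)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the structured reports.

    Returns the in-memory report dictionary; files written under
    ``config.output_dir``: coefficients, ANOVA, ridge path, optimum,
    serialized network, comparison report, scatter table, and a
    provenance block echoing versions, seeds and the configuration.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    factors = load_factors()
    if config.input_table is None:
        log.info("using packaged 27-run CCRD fixture")
        data = load_fixture("ccrd27")
    else:
        data = read_runs(config.input_table, factors)
    extra = None
    if config.validation_table == "fixture":
        extra = load_fixture("validation4")
    elif config.validation_table is not None:
        extra = read_runs(config.validation_table, factors)

    model = fit_quadratic(data)
    model.coefficients("coded").to_frame().join(
        model.coefficients("actual").to_frame()
    ).to_csv(out / "coefficients.csv")

    aov = anova(model, data)
    aov.table.to_csv(out / "anova.csv")
    _json_dump(aov.summary, out / "anova_summary.json")

    radii = np.linspace(
        config.ridge_radii_max / config.ridge_radii_n,
        config.ridge_radii_max,
        config.ridge_radii_n,
    )
    path = ridge_max(model, radii)
    path.samples.to_csv(out / "ridge_path.csv", index=False)

    opt = box_constrained_max(model, bounds=config.bounds, seed=config.design_seed)
    optimum = {
        "coded": opt.coded.tolist(),
        "actual": {f.name: float(a) for f, a in zip(factors, opt.actual)},
        "predicted_yield": opt.predicted,
        "on_boundary": opt.on_boundary.tolist(),
    }
    _json_dump(optimum, out / "optimum.json")

    ann = train_mlp(
        data,
        split=SplitSpec(*config.split, seed=config.ann_seed),
        hidden=config.hidden,
        restarts=config.restarts,
        seed=config.ann_seed,
    )
    (out / "ann_model.json").write_text(ann.to_json())

    report = compare_models(data, model, ann, extra=extra)
    _json_dump(report.as_dict(), out / "comparison.json")
    report.scatter.to_csv(out / "scatter.csv", index=False)

    provenance = {
        "rsmann_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": asdict(config),
    }
    _json_dump(provenance, out / "provenance.json")

    result = {
        "coefficients_actual": model.coefficients("actual").to_dict(),
        "anova_summary": aov.summary,
        "optimum": optimum,
        "ann_best_val_mse": ann.best_val_mse,
        "comparison": report.as_dict(),
        "provenance": provenance,
    }
    log.info(
        "pipeline done: RSM R²=%.4f, optimum %.2f mg/g, ANN val MSE=%.2e",
        aov.summary["r_squared"], opt.predicted, ann.best_val_mse,
    )
    return result


def build_design(config: PipelineConfig, randomize: bool = False) -> DesignTable:
    """Construct the CCRD named by the configuration (design stage)."""
    return build_ccrd(
        load_factors(),
        alpha=config.alpha,
        n_center=config.n_center,
        randomize=randomize,
        seed=config.design_seed,
    )
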