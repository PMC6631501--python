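"""Goodness-of-fit statistics for comparing surrogate models.

Three statistics are used to compare observed and predicted yields:

    R²   = 1 − Σ(Ypre − Yexp)² / Σ(Ym − Yexp)²,   Ym = mean(Yexp)
    RMSE = sqrt( Σ(Ypre − Yexp)² / n )            [mg/g]
    AAD  = 100 · mean( |Yexp − Ypre| / Ypre )     [%]

Note the AAD denominator is the *predicted* value, as conventionally
printed in the extraction-optimization literature; ``denominator=
"experimental"`` switches to the more common |err|/Yexp convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlp import MLPSurrogate
from .quadratic import ExperimentTable, QuadraticModel

__all__ = ["FitMetrics", "compute_metrics", "compare_models", "ComparisonReport"]


@dataclass(frozen=True)
class FitMetrics:
    """R²/RMSE/AAD summary for one (experimental, predicted) pairing."""

    n: int
    r_squared: float
    rmse: float
    aad: float
    mean_response: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "aad": self.aad,
            "mean_response": self.mean_response,
        }


def compute_metrics(
    experimental, predicted, denominator: str = "predicted"
) -> FitMetrics:
    """Compute R², RMSE (mg/g) and AAD (%) for paired yield vectors."""
    yexp = np.asarray(experimental, dtype=float)
    ypre = np.asarray(predicted, dtype=float)
    if yexp.shape != ypre.shape or yexp.ndim != 1 or len(yexp) < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    if denominator not in ("predicted", "experimental"):
        raise ValueError(f"unknown AAD denominator {denominator!r}")
    denom = ypre if denominator == "predicted" else yexp
    if np.any(denom == 0):
        raise ZeroDivisionError(
            f"AAD undefined: zero {denominator} value in the pairing"
        )
    err = ypre - yexp
    sse = float(err @ err)
    sst = float(((yexp - yexp.mean()) ** 2).sum())
    return FitMetrics(
        n=len(yexp),
        r_squared=1.0 - sse / sst,
        rmse=float(np.sqrt(sse / len(yexp))),
        aad=100.0 * float(np.mean(np.abs(err) / denom)),
        mean_response=float(yexp.mean()),
    )


@dataclass
class ComparisonReport:
    """Side-by-side fit statistics for the quadratic and network models."""

    metrics: dict[str, dict[str, FitMetrics]]  # dataset -> model -> metrics
    better: dict[str, dict[str, str]]          # dataset -> metric -> model name
    scatter: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "metrics": {
                ds: {m: fm.as_dict() for m, fm in by_model.items()}
                for ds, by_model in self.metrics.items()
            },
            "better": self.better,
        }


def _verdicts(by_model: dict[str, FitMetrics]) -> dict[str, str]:
    names = list(by_model)
    out = {}
    out["r_squared"] = max(names, key=lambda m: by_model[m].r_squared)
    out["rmse"] = min(names, key=lambda m: by_model[m].rmse)
    out["aad"] = min(names, key=lambda m: by_model[m].aad)
    return out


def compare_models(
    data: ExperimentTable,
    rsm: QuadraticModel,
    ann: MLPSurrogate,
    extra: ExperimentTable | None = None,
    pooled: bool = False,
) -> ComparisonReport:
    """Score both surrogates on the design runs (and, optionally, an
    external validation set), declare the better model per metric, and
    export an experimental-vs-predicted scatter table.

    Pooled metrics across design + validation runs are only computed on
    request; by default the two sets are kept separate.
    """
    sets: dict[str, ExperimentTable] = {"design": data}
    if extra is not None:
        sets["validation"] = extra

    metrics: dict[str, dict[str, FitMetrics]] = {}
    better: dict[str, dict[str, str]] = {}
    scatter_parts = []
    for ds_name, tbl in sets.items():
        x = tbl.design.actual
        yexp = tbl.response
        preds = {"rsm": np.asarray(rsm.predict(x)), "ann": np.asarray(ann.predict(x))}
        metrics[ds_name] = {
            m: compute_metrics(yexp, p) for m, p in preds.items()
        }
        better[ds_name] = _verdicts(metrics[ds_name])
        scatter_parts.append(
            pd.DataFrame(
                {
                    "dataset": ds_name,
                    "run_id": tbl.design.frame["run_id"].to_numpy(),
                    "experimental": yexp,
                    "rsm_pred": preds["rsm"],
                    "ann_pred": preds["ann"],
                }
            )
        )

    if pooled and extra is not None:
        x = np.vstack([data.design.actual, extra.design.actual])
        yexp = np.concatenate([data.response, extra.response])
        metrics["pooled"] = {
            "rsm": compute_metrics(yexp, rsm.predict(x)),
            "ann": compute_metrics(yexp, ann.predict(x)),
        }
        better["pooled"] = _verdicts(metrics["pooled"])

    return ComparisonReport(
        metrics=metrics, better=better, scatter=pd.concat(scatter_parts, ignore_index=True)
    )
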