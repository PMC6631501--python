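"""Packaged study fixtures and the synthetic CCRD generator.

Three delimited-text fixtures ship with the package:

* ``factors`` — coding metadata of the four extraction factors
  (temperature °C, ethanol %, liquid-to-solid ratio mL/g, ultrasonic
  power W), centers and per-coded-unit steps.
* ``ccrd27`` — the 27-run five-level CCRD with the measured chlorogenic
  acid yields (duplicate means ± sd, mg/g) plus the published
  quadratic-model and network predictions as reference columns.
* ``validation4`` — four external validation runs not part of the design.

Fixture files are integrity-checked against frozen SHA-256 digests at
load time.

The synthetic generator emulates the study's data-generating
assumptions: a known quadratic mean surface evaluated on a CCRD, plus
homoscedastic Gaussian replicate noise.  The default truth is the
published fitted surface, and the default noise scale (sd 0.12 mg/g on
a recorded duplicate mean) matches the pure-error mean square of the
study's center replicates; a high-noise preset matches the fit's
residual standard deviation (4.95 mg/g).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .design import DesignTable, FactorSpec, build_ccrd, _design_frame
from .quadratic import ExperimentTable, QuadraticModel

__all__ = [
    "CorruptedFixtureError",
    "load_fixture",
    "load_factors",
    "SyntheticSpec",
    "generate_synthetic",
    "STUDY_SURFACE_COEFS_ACTUAL",
    "NOISE_SD_PURE_ERROR",
    "NOISE_SD_RESIDUAL",
]


class CorruptedFixtureError(RuntimeError):
    """A packaged fixture file does not match its frozen checksum."""


_CHECKSUMS = {
    "factors.csv": "58e2775cc419876b1381fbca65ce8d76149054d3664445d538ae2b8b2f6060c1",
    "ccrd27.csv": "56e3834e63d1446eab622485c6264c1de2a083c50f3bac858d0ebbe9ba691449",
    "validation4.csv": "e8d25d0557c1f418b709af626c2328e09d12bcab73a7cad266c5e62434ddb5db",
}

# Published actual-unit coefficients of the fitted second-order surface,
# ordered: intercept; X1..X4; X1X2, X1X3, X1X4, X2X3, X2X4, X3X4; X1²..X4².
STUDY_SURFACE_COEFS_ACTUAL = np.array(
    [
        -344.708589,
        2.212185, 5.044251, 3.887346, 1.337813,
        0.008599, -0.017324, -0.011583, -0.012547, -0.000117, -0.006649,
        -0.007313, -0.03598, -0.015413, -0.002116,
    ]
)

#: sd (mg/g) of a recorded duplicate-mean response implied by the study's
#: center-replicate pure-error mean square (≈0.015 → sd ≈ 0.12).
NOISE_SD_PURE_ERROR = 0.12
#: high-noise preset: the quadratic fit's residual standard deviation.
NOISE_SD_RESIDUAL = 4.95

_FIXTURE_FILES = {
    "table1": "factors.csv",
    "factors": "factors.csv",
    "table2": "ccrd27.csv",
    "ccrd27": "ccrd27.csv",
    "table4": "validation4.csv",
    "validation4": "validation4.csv",
}


def _read_fixture(filename: str) -> pd.DataFrame:
    ref = resources.files("rsmann.data").joinpath(filename)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _CHECKSUMS[filename]
    if digest != expected:
        raise CorruptedFixtureError(
            f"fixture {filename}: sha256 {digest} != expected {expected}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_factors() -> list[FactorSpec]:
    """The four extraction factors with their coding metadata."""
    df = _read_fixture("factors.csv")
    return [
        FactorSpec(
            name=r["name"], unit=r["unit"], center=float(r["center"]),
            step=float(r["step"]), symbol=r["symbol"],
        )
        for _, r in df.iterrows()
    ]


def _experiment_from_frame(df: pd.DataFrame, factors: list[FactorSpec]) -> ExperimentTable:
    actual = df[[f.name for f in factors]].to_numpy(dtype=float)
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    coded = (actual - centers) / steps

    def block_of(z: np.ndarray) -> str:
        nz = np.flatnonzero(np.abs(z) > 1e-9)
        if len(nz) == 0:
            return "center"
        if np.all(np.isin(np.abs(z[nz]), [1.0])) and len(nz) == len(z):
            return "factorial"
        if len(nz) == 1:
            return "axial"
        return "external"

    blocks = [block_of(z) for z in coded]
    frame = _design_frame(factors, coded, blocks)
    frame["run_id"] = df["run"].to_numpy()
    design = DesignTable(factors=factors, frame=frame)
    return ExperimentTable(
        design=design,
        response=df["yield"].to_numpy(dtype=float),
        response_sd=df["yield_sd"].to_numpy(dtype=float),
        n_replicates=np.full(len(df), 2),
        extra=df,
    )


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``"table1"``/``"factors"`` → list of :class:`FactorSpec`;
    ``"table2"``/``"ccrd27"`` and ``"table4"``/``"validation4"`` →
    :class:`ExperimentTable` (published reference predictions are kept on
    ``.extra``).
    """
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(set(_FIXTURE_FILES))}"
        ) from None
    if filename == "factors.csv":
        return load_factors()
    return _experiment_from_frame(_read_fixture(filename), load_factors())


@dataclass
class SyntheticSpec:
    """Recipe for a simulated CCRD experiment.

    ``truth`` is the generating quadratic; ``noise_sd`` is the standard
    deviation (mg/g) of a *recorded* response.  When ``replicates > 1``
    each run's individual determinations are drawn with sd
    ``noise_sd·√replicates`` so their mean keeps sd ``noise_sd``.
    """

    factors: list[FactorSpec] = field(default_factory=load_factors)
    truth: QuadraticModel | None = None
    noise_sd: float = NOISE_SD_PURE_ERROR
    alpha: float | None = None
    n_center: int = 3
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.truth is None:
            self.truth = QuadraticModel.from_actual_coefs(
                self.factors, STUDY_SURFACE_COEFS_ACTUAL
            )


def generate_synthetic(spec: SyntheticSpec) -> ExperimentTable:
    """Simulate a CCRD experiment from a known quadratic truth.

    Responses are ``truth(x) + iid Gaussian noise``; recorded values are
    replicate means (with per-run sd when ``replicates > 1``).  Negative
    draws are kept as-is only if non-negative truth allows; the recorded
    response is clipped at 0 to respect the yield domain.  Deterministic
    per seed.
    """
    assert spec.truth is not None
    design = build_ccrd(
        spec.factors, alpha=spec.alpha, n_center=spec.n_center,
    )
    rng = np.random.default_rng(spec.seed)
    mu = np.asarray(spec.truth.predict(design.actual))
    r = spec.replicates
    if spec.noise_sd == 0:
        response = mu.copy()
        sd = np.zeros_like(mu)
    else:
        draws = rng.normal(
            loc=mu[:, None], scale=spec.noise_sd * np.sqrt(r), size=(len(mu), r)
        )
        response = draws.mean(axis=1)
        sd = draws.std(axis=1, ddof=1) if r > 1 else np.zeros_like(mu)
    response = np.clip(response, 0.0, None)
    return ExperimentTable(
        design=design,
        response=response,
        response_sd=sd,
        n_replicates=np.full(len(mu), r),
    )
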