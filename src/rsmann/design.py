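"""Central composite rotatable designs (CCRD) and factor coding.

A CCRD for ``k`` factors consists of a full two-level factorial cube
(coded levels −1/+1), ``2k`` axial (star) points at coded distance
±α on each axis, and ``n_center`` replicated center points.  With
α = (2^k)^(1/4) the design is rotatable: the prediction variance of a
second-order fit depends only on the distance from the design center.

Factors are handled in *coded units* internally.  A :class:`FactorSpec`
maps a coded value ``c`` to an actual setting ``center + c * step``, so
five coded levels −2…+2 span the experimental range of the factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "InvalidDesignError",
    "build_ccrd",
    "rotatable_alpha",
]


class InvalidDesignError(ValueError):
    """Raised for an unusable factor or design specification."""


@dataclass(frozen=True)
class FactorSpec:
    """Coding metadata for one experimental factor.

    Parameters
    ----------
    name : str
        Human-readable factor name (e.g. ``"temperature"``).
    unit : str
        Unit of the actual scale (°C, %, mL/g, W, ...).
    center : float
        Actual value at coded 0.
    step : float
        Actual increment per coded unit; must be positive.
    symbol : str
        Short design symbol (``"X1"`` ... ``"Xk"``).
    """

    name: str
    unit: str
    center: float
    step: float
    symbol: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.step) or self.step <= 0:
            raise InvalidDesignError(
                f"factor {self.name!r}: step must be positive, got {self.step}"
            )

    def to_coded(self, actual):
        """Map actual units to coded units, ``(actual − center) / step``."""
        return (np.asarray(actual, dtype=float) - self.center) / self.step

    def to_actual(self, coded):
        """Inverse of :meth:`to_coded`."""
        return self.center + np.asarray(coded, dtype=float) * self.step

    def levels(self, alpha: float = 2.0) -> np.ndarray:
        """The five actual levels at coded −α, −1, 0, +1, +α."""
        return self.to_actual(np.array([-alpha, -1.0, 0.0, 1.0, alpha]))


def rotatable_alpha(k: int) -> float:
    """Axial distance (2^k)^(1/4) that makes the CCRD rotatable."""
    return (2.0**k) ** 0.25


@dataclass
class DesignTable:
    """A realized design: factor specs plus one row per experimental run.

    ``frame`` holds columns ``run_id``, ``block`` and, per factor,
    ``<symbol>_coded`` and ``<symbol>_actual``.
    """

    factors: list[FactorSpec]
    frame: pd.DataFrame = field(repr=False)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, k) coded settings."""
        cols = [f"{f.symbol}_coded" for f in self.factors]
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def actual(self) -> np.ndarray:
        """(n_runs, k) actual-unit settings."""
        cols = [f"{f.symbol}_actual" for f in self.factors]
        return self.frame[cols].to_numpy(dtype=float)

    def to_coded(self, actual) -> np.ndarray:
        """Vectorized actual→coded conversion for (..., k) settings."""
        actual = np.atleast_2d(np.asarray(actual, dtype=float))
        centers = np.array([f.center for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        return (actual - centers) / steps

    def to_actual(self, coded) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        centers = np.array([f.center for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        return centers + coded * steps

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _design_frame(factors: list[FactorSpec], coded: np.ndarray, blocks: list[str]) -> pd.DataFrame:
    data: dict[str, object] = {
        "run_id": np.arange(1, len(coded) + 1),
        "block": blocks,
    }
    for j, f in enumerate(factors):
        data[f"{f.symbol}_coded"] = coded[:, j]
        data[f"{f.symbol}_actual"] = f.to_actual(coded[:, j])
    return pd.DataFrame(data)


def build_ccrd(
    factors: list[FactorSpec],
    alpha: float | None = None,
    n_center: int = 3,
    randomize: bool = False,
    seed: int | None = None,
) -> DesignTable:
    """Construct a central composite design in coded and actual units.

    Parameters
    ----------
    factors : list of FactorSpec
        The ``k`` factors (2 ≤ k ≤ 8).
    alpha : float, optional
        Axial distance; defaults to the rotatable value (2^k)^(1/4).
    n_center : int
        Number of replicated center runs (supplies pure error).
    randomize : bool
        Permute run order reproducibly from ``seed``.  The default keeps
        the systematic factorial → axial → center order; least-squares
        fitting is invariant to run order.

    Returns
    -------
    DesignTable
        ``2^k + 2k + n_center`` runs tagged ``factorial``/``axial``/``center``.
    """
    k = len(factors)
    if not 2 <= k <= 8:
        raise InvalidDesignError(f"need 2..8 factors, got {k}")
    if alpha is None:
        alpha = rotatable_alpha(k)
    if not np.isfinite(alpha) or alpha <= 0:
        raise InvalidDesignError(f"alpha must be positive, got {alpha}")
    if int(n_center) != n_center or n_center <= 0:
        raise InvalidDesignError(f"n_center must be a positive integer, got {n_center}")
    n_center = int(n_center)

    cube = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha
    center = np.zeros((n_center, k))

    coded = np.vstack([cube, axial, center])
    blocks = ["factorial"] * len(cube) + ["axial"] * len(axial) + ["center"] * n_center

    if randomize:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(coded))
        coded = coded[order]
        blocks = [blocks[i] for i in order]

    return DesignTable(factors=list(factors), frame=_design_frame(factors, coded, blocks))
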