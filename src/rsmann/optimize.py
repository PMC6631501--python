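"""Stationary-point, ridge, and box-constrained optimization of a
fitted second-order surface.

All computation happens in coded units, where the model is

    ŷ(z) = b0 + b'z + z'Bz,

with B symmetric (interaction coefficients halved off the diagonal).

Ridge (max) analysis follows the classical second-order formulation:
for each radius r the constrained maximum of ŷ on the sphere ‖z‖ = r
satisfies the Lagrangian system (μI − B) z = b/2 for a multiplier μ
strictly above the largest eigenvalue of B; ‖z(μ)‖ is strictly
decreasing on that branch, so μ is found by scalar root-finding on
‖z(μ)‖ = r.

The "optimal conditions" of an extraction study are usually reported
inside the coded hypercube rather than on a sphere, so a multi-start
box-constrained maximizer over [−2, +2]^k is provided as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .quadratic import QuadraticModel

__all__ = [
    "CanonicalAnalysis",
    "RidgePath",
    "Optimum",
    "canonical_analysis",
    "ridge_max",
    "box_constrained_max",
]


@dataclass
class CanonicalAnalysis:
    """Stationary point of the quadratic surface and its nature."""

    stationary_coded: np.ndarray | None
    stationary_actual: np.ndarray | None
    predicted: float | None
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    nature: str  # "maximum" | "minimum" | "saddle" | "degenerate"
    degenerate: bool = False


def canonical_analysis(
    model: QuadraticModel, singular_tol: float = 1e-10
) -> CanonicalAnalysis:
    """Solve the zero-gradient condition 2Bz = −b and classify it.

    A (numerically) singular quadratic form has no unique stationary
    point; the result is then flagged degenerate and carries only the
    eigen-decomposition.
    """
    _, b, B = model.quadratic_form
    evals, evecs = np.linalg.eigh(B)
    scale = max(np.abs(evals).max(), 1.0)
    if np.abs(evals).min() <= singular_tol * scale:
        return CanonicalAnalysis(
            stationary_coded=None,
            stationary_actual=None,
            predicted=None,
            eigenvalues=evals,
            eigenvectors=evecs,
            nature="degenerate",
            degenerate=True,
        )
    zs = np.linalg.solve(-2.0 * B, b)
    if np.all(evals < 0):
        nature = "maximum"
    elif np.all(evals > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    return CanonicalAnalysis(
        stationary_coded=zs,
        stationary_actual=model.factors and np.array(
            [f.to_actual(zs[j]) for j, f in enumerate(model.factors)]
        ),
        predicted=model.predict(zs, space="coded"),
        eigenvalues=evals,
        eigenvectors=evecs,
        nature=nature,
    )


@dataclass
class RidgePath:
    """Constrained maxima of the surface on spheres of increasing radius."""

    samples: pd.DataFrame = field(repr=False)
    eigenvalues: np.ndarray | None = None
    stationary: CanonicalAnalysis | None = None


def _ridge_point(b: np.ndarray, B: np.ndarray, lam_max: float, r: float) -> np.ndarray:
    """Max of b'z + z'Bz on ‖z‖ = r via the μ > λ_max Lagrangian branch."""
    k = len(b)
    eye = np.eye(k)

    def norm_at(mu: float) -> float:
        return float(np.linalg.norm(np.linalg.solve(mu * eye - B, b / 2.0)))

    # ‖z(μ)‖ → ∞ as μ → λ_max⁺ (generic b) and → 0 as μ → ∞.
    lo = lam_max + 1e-12
    tries = 0
    while norm_at(lo) < r:
        # b orthogonal-ish to the top eigenvector: shrink toward λ_max
        lo = lam_max + (lo - lam_max) / 10.0
        tries += 1
        if tries > 200:
            raise RuntimeError(f"no ridge solution at radius {r}")
    hi = lam_max + max(1.0, 2 * np.abs(lam_max))
    while norm_at(hi) > r:
        hi = lam_max + (hi - lam_max) * 2.0
    mu = brentq(lambda m: norm_at(m) - r, lo, hi, xtol=1e-13, maxiter=200)
    return np.linalg.solve(mu * eye - B, b / 2.0)


def ridge_max(model: QuadraticModel, radii) -> RidgePath:
    """Trace the ridge of maxima over the given increasing coded radii.

    Radii where the Lagrangian root-finding fails are kept in the path
    with NaN coordinates and ``ok=False`` rather than dropped silently.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) == 0 or np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    _, b, B = model.quadratic_form
    lam_max = float(np.linalg.eigvalsh(B).max())

    rows = []
    syms = [f.symbol for f in model.factors]
    for r in radii:
        try:
            z = _ridge_point(b, B, lam_max, float(r))
            ok = True
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            warnings.warn(f"ridge solve failed at radius {r}: {err}")
            z = np.full(model.k, np.nan)
            ok = False
        row: dict[str, float | bool] = {"radius": float(r), "ok": ok}
        for j, s in enumerate(syms):
            row[f"{s}_coded"] = z[j]
            row[f"{s}_actual"] = model.factors[j].to_actual(z[j])
        row["predicted"] = (
            model.predict(z, space="coded") if ok else np.nan
        )
        rows.append(row)
    return RidgePath(
        samples=pd.DataFrame(rows),
        eigenvalues=np.linalg.eigvalsh(B),
        stationary=canonical_analysis(model),
    )


@dataclass
class Optimum:
    """Result of box-constrained maximization of the fitted surface."""

    coded: np.ndarray
    actual: np.ndarray
    predicted: float
    on_boundary: np.ndarray  # per-factor: -1 lower face, +1 upper face, 0 interior


def box_constrained_max(
    model: QuadraticModel,
    bounds: tuple[float, float] | list[tuple[float, float]] = (-2.0, 2.0),
    n_starts: int = 64,
    seed: int = 0,
    gtol: float = 1e-10,
) -> Optimum:
    """Global maximum of the quadratic over a coded box by multi-start
    local optimization (L-BFGS-B with analytic gradients).

    Starts cover the 3^k lattice of face/edge/center points (capped)
    plus seeded uniform draws.  A quadratic over a box at this scale is
    solved reliably by this scheme.
    """
    k = model.k
    if isinstance(bounds, tuple) and np.isscalar(bounds[0]):
        box = [(float(bounds[0]), float(bounds[1]))] * k
    else:
        box = [(float(lo), float(hi)) for lo, hi in bounds]
    if any(hi <= lo for lo, hi in box):
        raise ValueError("each bound must satisfy lo < hi")

    b0, b, B = model.quadratic_form

    def neg(z: np.ndarray) -> tuple[float, np.ndarray]:
        return -(b0 + b @ z + z @ B @ z), -(b + 2.0 * B @ z)

    rng = np.random.default_rng(seed)
    lattice = (
        np.array(
            np.meshgrid(*[[lo, (lo + hi) / 2, hi] for lo, hi in box], indexing="ij")
        )
        .reshape(k, -1)
        .T
    )
    if len(lattice) > n_starts:
        lattice = lattice[rng.choice(len(lattice), n_starts, replace=False)]
    randoms = rng.uniform(
        [lo for lo, _ in box], [hi for _, hi in box], size=(n_starts, k)
    )
    starts = np.vstack([lattice, randoms])

    best_z, best_f = None, np.inf
    for z0 in starts:
        res = minimize(
            neg, z0, jac=True, method="L-BFGS-B", bounds=box,
            options={"gtol": gtol, "ftol": 0.0, "maxiter": 500},
        )
        if res.fun < best_f:
            best_f, best_z = res.fun, res.x
    assert best_z is not None

    on_bound = np.zeros(k, dtype=int)
    for j, (lo, hi) in enumerate(box):
        tol = 1e-8 * (hi - lo)
        if best_z[j] <= lo + tol:
            on_bound[j] = -1
        elif best_z[j] >= hi - tol:
            on_bound[j] = 1
    actual = np.array([f.to_actual(best_z[j]) for j, f in enumerate(model.factors)])
    return Optimum(
        coded=best_z, actual=actual, predicted=float(-best_f), on_boundary=on_bound
    )
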