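"""Second-order response-surface fitting, prediction and ANOVA diagnostics.

The model is the full quadratic polynomial in ``k`` factors

    y = β0 + Σ βi xi + Σ_{i<j} βij xi xj + Σ βii xi²

(15 coefficients for k = 4), fitted by ordinary least squares in coded
units for numerical conditioning.  Coefficients convert exactly between
coded and actual space (the map is linear in the coefficient vector).

The ANOVA decomposes the corrected total sum of squares into model and
residual parts, the residual further into lack of fit and pure error
(pure error pooled from replicated design points, typically the center
replicates), and reports per-term partial (Type-III) sums of squares:
the extra sum of squares from deleting that single term from the full
model, computed as βj² / [(X'X)⁻¹]jj.  PRESS is the leave-one-out
prediction error sum of squares via the hat-matrix shortcut
Σ (e_i / (1 − h_ii))².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable, FactorSpec

__all__ = [
    "ExperimentTable",
    "QuadraticModel",
    "AnovaTable",
    "SingularFitError",
    "term_names",
    "quadratic_design_matrix",
    "fit_quadratic",
    "anova",
    "evaluate_surface_grid",
]


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the quadratic design matrix is rank deficient."""


@dataclass
class ExperimentTable:
    """A design plus its measured responses (mg/g), one row per run.

    ``response`` holds the per-run mean (of duplicates, where measured in
    replicate); ``response_sd`` and ``n_replicates`` are optional
    annotations carried through for reporting.
    """

    design: DesignTable
    response: np.ndarray
    response_sd: np.ndarray | None = None
    n_replicates: np.ndarray | None = None
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if len(self.response) != self.design.n_runs:
            raise ValueError(
                f"{len(self.response)} responses for {self.design.n_runs} runs"
            )
        if not np.all(np.isfinite(self.response)) or np.any(self.response < 0):
            raise ValueError("responses must be finite and non-negative")
        if self.response_sd is not None:
            self.response_sd = np.asarray(self.response_sd, dtype=float)

    @property
    def factors(self) -> list[FactorSpec]:
        return self.design.factors


def term_names(factors: list[FactorSpec]) -> list[str]:
    """Term labels in model order: 1, X1.., XiXj (i<j), X1^2.. ."""
    syms = [f.symbol for f in factors]
    k = len(syms)
    names = ["Intercept"] + syms
    names += [f"{syms[i]}{syms[j]}" for i in range(k) for j in range(i + 1, k)]
    names += [f"{s}^2" for s in syms]
    return names


def quadratic_design_matrix(x: np.ndarray) -> np.ndarray:
    """Expand (n, k) settings into the (n, 1+2k+k(k-1)/2) model matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, k = x.shape
    cols = [np.ones(n)]
    cols += [x[:, i] for i in range(k)]
    cols += [x[:, i] * x[:, j] for i in range(k) for j in range(i + 1, k)]
    cols += [x[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


def _n_terms(k: int) -> int:
    return 1 + 2 * k + k * (k - 1) // 2


def _coded_to_actual_coefs(beta: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Exact coefficient transform from coded space to actual units.

    Substituting z_i = (x_i − c_i)/s_i into the coded-space polynomial and
    collecting powers of x gives closed-form expressions for every actual
    coefficient; the map is linear and invertible.
    """
    k = len(factors)
    c = np.array([f.center for f in factors])
    s = np.array([f.step for f in factors])
    b0 = beta[0]
    lin = beta[1 : 1 + k]
    inter = np.zeros((k, k))
    idx = 1 + k
    for i in range(k):
        for j in range(i + 1, k):
            inter[i, j] = beta[idx]
            idx += 1
    quad = beta[idx : idx + k]

    a0 = b0 - np.sum(lin * c / s) + np.sum(quad * (c / s) ** 2)
    a_lin = lin / s - 2 * quad * c / s**2
    a_inter = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a0 += inter[i, j] * c[i] * c[j] / (s[i] * s[j])
            a_lin[i] -= inter[i, j] * c[j] / (s[i] * s[j])
            a_lin[j] -= inter[i, j] * c[i] / (s[i] * s[j])
            a_inter[i, j] = inter[i, j] / (s[i] * s[j])
    a_quad = quad / s**2

    out = [a0] + list(a_lin)
    out += [a_inter[i, j] for i in range(k) for j in range(i + 1, k)]
    out += list(a_quad)
    return np.array(out)


@dataclass
class QuadraticModel:
    """A fitted (or specified) full second-order polynomial.

    ``beta_coded`` is the canonical coefficient vector in coded units,
    ordered as :func:`term_names`.  ``beta_actual`` is derived exactly.
    """

    factors: list[FactorSpec]
    beta_coded: np.ndarray
    df_residual: int | None = None

    def __post_init__(self) -> None:
        self.beta_coded = np.asarray(self.beta_coded, dtype=float)
        if len(self.beta_coded) != _n_terms(len(self.factors)):
            raise ValueError(
                f"expected {_n_terms(len(self.factors))} coefficients, "
                f"got {len(self.beta_coded)}"
            )

    @classmethod
    def from_actual_coefs(
        cls, factors: list[FactorSpec], beta_actual: np.ndarray
    ) -> "QuadraticModel":
        """Build a model from actual-unit coefficients (exact inverse map)."""
        # A quadratic in actual units is a quadratic in coded units, so
        # interpolating exact evaluations at a full-rank coded point set
        # recovers the coded coefficients to machine precision.
        from .design import build_ccrd

        k = len(factors)
        dummy = build_ccrd(factors, n_center=1)
        z = np.vstack([dummy.coded, 0.5 * dummy.coded + 0.25])
        actual = np.column_stack([factors[j].to_actual(z[:, j]) for j in range(k)])
        y = quadratic_design_matrix(actual) @ np.asarray(beta_actual, dtype=float)
        beta_coded, *_ = np.linalg.lstsq(quadratic_design_matrix(z), y, rcond=None)
        return cls(factors=list(factors), beta_coded=beta_coded)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def term_names(self) -> list[str]:
        return term_names(self.factors)

    @property
    def beta_actual(self) -> np.ndarray:
        return _coded_to_actual_coefs(self.beta_coded, self.factors)

    def coefficients(self, space: str = "coded") -> pd.Series:
        beta = self.beta_coded if space == "coded" else self.beta_actual
        return pd.Series(beta, index=self.term_names, name=f"beta_{space}")

    # quadratic-form pieces (coded space): y = b0 + b'z + z' B z
    @property
    def quadratic_form(self) -> tuple[float, np.ndarray, np.ndarray]:
        k = self.k
        b0 = self.beta_coded[0]
        b = self.beta_coded[1 : 1 + k].copy()
        B = np.zeros((k, k))
        idx = 1 + k
        for i in range(k):
            for j in range(i + 1, k):
                B[i, j] = B[j, i] = self.beta_coded[idx] / 2.0
                idx += 1
        np.fill_diagonal(B, self.beta_coded[idx : idx + k])
        return b0, b, B

    def predict(self, settings, space: str = "actual") -> np.ndarray | float:
        """Evaluate the surface at one or many settings.

        ``space`` names the units of ``settings``; output is always mg/g.
        """
        x = np.asarray(settings, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.k:
            raise ValueError(f"settings must have {self.k} columns")
        if space == "actual":
            centers = np.array([f.center for f in self.factors])
            steps = np.array([f.step for f in self.factors])
            z = (x - centers) / steps
        elif space == "coded":
            z = x
        else:
            raise ValueError(f"unknown space {space!r}")
        y = quadratic_design_matrix(z) @ self.beta_coded
        return float(y[0]) if single else y


def fit_quadratic(data: ExperimentTable) -> QuadraticModel:
    """Ordinary least-squares fit of the full quadratic in coded units.

    Raises
    ------
    SingularFitError
        If the model matrix is rank deficient; the message names the
        dependent columns found by pivoted QR.
    """
    z = data.design.coded
    y = data.response
    X = quadratic_design_matrix(z)
    p = X.shape[1]
    if len(y) < p + 1:
        raise ValueError(
            f"need at least {p + 1} runs to fit {p} coefficients with ≥1 residual df"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        import scipy.linalg as sla

        _, _, piv = sla.qr(X, pivoting=True)
        names = term_names(data.factors)
        bad = sorted(names[i] for i in piv[rank:])
        raise SingularFitError(
            f"design matrix rank {rank} < {p}; collinear columns: {', '.join(bad)}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return QuadraticModel(
        factors=list(data.factors), beta_coded=beta, df_residual=len(y) - p
    )


@dataclass
class AnovaTable:
    """Sum-of-squares decomposition and summary diagnostics of a fit."""

    table: pd.DataFrame
    summary: dict[str, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [self.table.to_string(float_format=lambda v: f"{v:.4f}")]
        lines += [f"{k}: {v:.4f}" for k, v in self.summary.items()]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical design points (for pure error)."""
    df = pd.DataFrame(np.round(coded, 10))
    groups = df.groupby(list(df.columns), sort=False).indices
    return [np.asarray(ix) for ix in groups.values() if len(ix) > 1]


def anova(model: QuadraticModel, data: ExperimentTable) -> AnovaTable:
    """Full ANOVA of a quadratic fit: per-term partial SS, lack of fit,
    pure error, and the summary diagnostics (R², Adj R², PRESS, CV%...).

    Lack-of-fit rows require replicated design points; with zero pure-error
    degrees of freedom the corresponding F and p are reported as NaN.
    """
    z = data.design.coded
    y = data.response
    X = quadratic_design_matrix(z)
    n, p = X.shape
    beta = model.beta_coded

    fitted = X @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_tot - ss_res
    df_model, df_res = p - 1, n - p
    ms_model, ms_res = ss_model / df_model, ss_res / df_res

    XtX_inv = np.linalg.inv(X.T @ X)
    hat = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    press = float(((resid / (1.0 - hat)) ** 2).sum())

    rows: list[dict[str, float | str]] = []
    f_model = ms_model / ms_res
    rows.append(
        dict(
            source="Model",
            ss=ss_model,
            df=df_model,
            ms=ms_model,
            F=f_model,
            p=float(stats.f.sf(f_model, df_model, df_res)),
        )
    )
    names = model.term_names
    for j in range(1, p):  # every non-intercept term
        ss_j = float(beta[j] ** 2 / XtX_inv[j, j])
        f_j = ss_j / ms_res
        rows.append(
            dict(
                source=names[j],
                ss=ss_j,
                df=1,
                ms=ss_j,
                F=f_j,
                p=float(stats.f.sf(f_j, 1, df_res)),
            )
        )
    rows.append(dict(source="Residual", ss=ss_res, df=df_res, ms=ms_res, F=np.nan, p=np.nan))

    groups = _replicate_groups(z)
    ss_pe = sum(float(((y[ix] - y[ix].mean()) ** 2).sum()) for ix in groups)
    df_pe = sum(len(ix) - 1 for ix in groups)
    ss_lof = ss_res - ss_pe
    df_lof = df_res - df_pe
    if df_pe > 0 and df_lof > 0:
        ms_pe = ss_pe / df_pe
        ms_lof = ss_lof / df_lof
        f_lof = ms_lof / ms_pe if ms_pe > 0 else np.inf
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        ms_pe = ss_pe / df_pe if df_pe else np.nan
        ms_lof = f_lof = p_lof = np.nan
    rows.append(dict(source="Lack of Fit", ss=ss_lof, df=df_lof, ms=ms_lof, F=f_lof, p=p_lof))
    rows.append(
        dict(source="Pure Error", ss=ss_pe, df=df_pe, ms=ms_pe, F=np.nan, p=np.nan)
    )
    rows.append(dict(source="Cor Total", ss=ss_tot, df=n - 1, ms=np.nan, F=np.nan, p=np.nan))

    table = pd.DataFrame(rows).set_index("source")
    mean_y = float(y.mean())
    summary = {
        "r_squared": 1.0 - ss_res / ss_tot,
        "adj_r_squared": 1.0 - (ss_res / df_res) / (ss_tot / (n - 1)),
        "press": press,
        "std_dev": float(np.sqrt(ms_res)),
        "mean": mean_y,
        "cv_percent": 100.0 * float(np.sqrt(ms_res)) / mean_y,
    }
    return AnovaTable(table=table, summary=summary)


def evaluate_surface_grid(
    model: QuadraticModel,
    vary: tuple[str, str],
    fixed: dict[str, float] | None = None,
    resolution: int = 50,
    bounds: tuple[float, float] = (-2.0, 2.0),
    fixed_space: str = "actual",
) -> pd.DataFrame:
    """Predicted-yield grid over two factors with the others held fixed.

    ``vary`` names two factor symbols; the grid spans ``bounds`` in coded
    units (converted to actual units in the output).  ``fixed`` gives the
    held factors' settings in ``fixed_space`` units; unspecified factors
    sit at their centers.
    """
    syms = [f.symbol for f in model.factors]
    s1, s2 = vary
    if s1 == s2 or s1 not in syms or s2 not in syms:
        raise ValueError(f"vary must name two distinct factors among {syms}")
    i1, i2 = syms.index(s1), syms.index(s2)

    fixed = dict(fixed or {})
    z_fixed = np.zeros(len(syms))
    for sym, val in fixed.items():
        j = syms.index(sym)
        z_fixed[j] = (
            model.factors[j].to_coded(val) if fixed_space == "actual" else float(val)
        )

    grid1 = np.linspace(bounds[0], bounds[1], resolution)
    grid2 = np.linspace(bounds[0], bounds[1], resolution)
    g1, g2 = np.meshgrid(grid1, grid2, indexing="ij")
    pts = np.tile(z_fixed, (resolution * resolution, 1))
    pts[:, i1] = g1.ravel()
    pts[:, i2] = g2.ravel()
    yhat = model.predict(pts, space="coded")

    f1, f2 = model.factors[i1], model.factors[i2]
    return pd.DataFrame(
        {
            f"{s1}_coded": pts[:, i1],
            f"{s2}_coded": pts[:, i2],
            f"{s1}_actual": f1.to_actual(pts[:, i1]),
            f"{s2}_actual": f2.to_actual(pts[:, i2]),
            "predicted": yhat,
        }
    )
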