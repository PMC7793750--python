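"""Maximum-likelihood linear-quadratic dose-response fitting.

The calibration model for low-LET radiation is the linear-quadratic (LQ)
yield curve

    Y(D) = C + alpha * D + beta * D**2

fitted to aggregated per-dose counts ``(D_i, N_i cells, X_i dicentrics)`` by
maximizing the Poisson log-likelihood with the cell number as exposure
(identity link):

    l(C, alpha, beta) = sum_i [ X_i * ln(N_i * Yhat_i) - N_i * Yhat_i ]

The maximizer is found by iteratively reweighted least squares (IRLS) on the
observed yields with weights ``N_i / Yhat_i``, which is the scoring algorithm
for this GLM and is deterministic.  Coefficients are constrained to be
non-negative: an iterate that converges to a negative coefficient is projected
to zero and the reduced model is refitted.

The coefficient covariance is the inverse observed Fisher information at the
optimum.  For heavily overdispersed tables a quasi-Poisson covariance
(scaled by Pearson chi2 / dof) is available via ``dispersion_scale=True``;
it is off by default because the reference curves are fitted as plain
Poisson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .counts import DicentricCountTable, validate_table
from .exceptions import (
    DegenerateFitError,
    DCACalibError,
    FitConvergenceError,
    InvalidCountData,
)

__all__ = [
    "CalibrationCurve",
    "FitDiagnostics",
    "fit_lq",
    "predict_yield",
    "goodness_of_fit",
    "curve_confidence_band",
]

_ORDERS = {"linear": 2, "linear-quadratic": 3}
_YIELD_FLOOR = 1e-12


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted (or externally supplied) LQ dose-response curve.

    ``covariance`` is the symmetric 3x3 coefficient covariance matrix in the
    order (C, alpha, beta); for a linear curve the beta row/column is zero.
    Curves built from published coefficients and standard errors carry a
    diagonal covariance.
    """

    c: float
    alpha: float
    beta: float
    covariance: np.ndarray | None = None
    order: str = "linear-quadratic"
    loglik: float | None = None
    n_free_parameters: int = 3
    n_iterations: int | None = None

    def __post_init__(self):
        if self.order not in _ORDERS:
            raise InvalidCountData(f"unknown model order {self.order!r}")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (3, 3):
                raise InvalidCountData("covariance must be 3x3 in (C, alpha, beta)")
            object.__setattr__(self, "covariance", cov)
        for name in ("c", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise InvalidCountData(f"coefficient {name} must be non-negative")

    @classmethod
    def from_coefficients(
        cls,
        c: float,
        alpha: float,
        beta: float = 0.0,
        se_c: float = 0.0,
        se_alpha: float = 0.0,
        se_beta: float = 0.0,
        order: str | None = None,
    ) -> "CalibrationCurve":
        """Build a curve from published coefficients and standard errors.

        The covariance is diagonal (published reports rarely include the
        off-diagonal terms).
        """
        if order is None:
            order = "linear" if beta == 0 else "linear-quadratic"
        cov = np.diag([se_c**2, se_alpha**2, se_beta**2])
        n_free = 2 if order == "linear" else 3
        return cls(c, alpha, beta, covariance=cov, order=order, n_free_parameters=n_free)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.c, self.alpha, self.beta])

    @property
    def se_c(self) -> float:
        return self._se(0)

    @property
    def se_alpha(self) -> float:
        return self._se(1)

    @property
    def se_beta(self) -> float:
        return self._se(2)

    def _se(self, i: int) -> float:
        if self.covariance is None:
            return float("nan")
        return float(np.sqrt(self.covariance[i, i]))

    def predict(self, dose):
        return predict_yield(self, dose)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coefficients": {"c": self.c, "alpha": self.alpha, "beta": self.beta},
            "standard_errors": {
                "c": self.se_c,
                "alpha": self.se_alpha,
                "beta": self.se_beta,
            },
            "covariance": None
            if self.covariance is None
            else self.covariance.tolist(),
            "loglik": self.loglik,
            "n_free_parameters": self.n_free_parameters,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        coef = d["coefficients"]
        cov = d.get("covariance")
        return cls(
            c=coef["c"],
            alpha=coef["alpha"],
            beta=coef["beta"],
            covariance=None if cov is None else np.asarray(cov),
            order=d.get("order", "linear-quadratic"),
            loglik=d.get("loglik"),
            n_free_parameters=d.get("n_free_parameters", 3),
        )


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness of fit and coefficient tests for a fitted curve."""

    pearson_chi2: float
    dof: int
    p_value: float
    fitted_yields: np.ndarray
    pearson_residuals: np.ndarray
    coef_z: dict
    coef_p: dict


def _design(doses: np.ndarray, n_coef: int) -> np.ndarray:
    cols = [np.ones_like(doses), doses, doses**2]
    return np.column_stack(cols[:n_coef])


def _loglik(x: np.ndarray, n: np.ndarray, yhat: np.ndarray) -> float:
    yhat = np.maximum(yhat, _YIELD_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(n * yhat), 0.0) - n * yhat
    return float(terms.sum())


def _irls(
    doses: np.ndarray,
    n: np.ndarray,
    x: np.ndarray,
    free: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, list]:
    """IRLS over the free coefficients; fixed coefficients are held at 0."""
    y = x / n
    g_full = _design(doses, free.size)
    g = g_full[:, free]
    # start from unweighted least squares on yields clipped away from zero
    b = np.linalg.lstsq(g, np.maximum(y, 1e-6), rcond=None)[0]
    trace = [b.copy()]
    for it in range(1, max_iter + 1):
        yhat = np.maximum(g @ b, _YIELD_FLOOR)
        w = n / yhat
        wg = g * w[:, None]
        b_new = np.linalg.solve(g.T @ wg, wg.T @ y)
        trace.append(b_new.copy())
        denom = np.maximum(np.abs(b_new), 1e-12)
        if np.max(np.abs(b_new - b) / denom) < tol:
            return b_new, it, trace
        b = b_new
    raise FitConvergenceError(
        f"IRLS did not converge within {max_iter} iterations", trace=trace
    )


def fit_lq(
    table: DicentricCountTable,
    order: str = "linear-quadratic",
    dispersion_scale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> CalibrationCurve:
    """Fit the LQ (or linear) curve to a count table by Poisson ML.

    Parameters
    ----------
    table
        Validated dicentric count table; needs at least ``order + 1``
        distinct doses and at least one row with dicentrics.
    order
        ``"linear-quadratic"`` (default) or ``"linear"`` (beta fixed at 0).
    dispersion_scale
        If True, multiply the covariance by ``max(1, Pearson chi2 / dof)``
        (quasi-Poisson correction for overdispersed tables).
    """
    validate_table(table)
    if order not in _ORDERS:
        raise InvalidCountData(f"unknown model order {order!r}")
    n_coef = _ORDERS[order]
    doses, n, x = table.doses, table.cells.astype(float), table.dicentrics.astype(float)
    if len(doses) < n_coef:
        raise InvalidCountData(
            f"{order} fit needs at least {n_coef} distinct doses, got {len(doses)}"
        )
    if x.sum() == 0:
        raise InvalidCountData("cannot fit a curve to a table with no dicentrics")

    free = np.arange(n_coef)
    while True:
        b, it, trace = _irls(doses, n, x, free, tol, max_iter)
        if np.all(b >= 0) or free.size == 1:
            break
        # project the most negative coefficient to zero, refit reduced model
        free = np.delete(free, int(np.argmin(b)))
    b = np.maximum(b, 0.0)

    g = _design(doses, n_coef)[:, free]
    yhat = np.maximum(g @ b, _YIELD_FLOOR)
    # observed Fisher information of the aggregated Poisson log-likelihood
    info = (g.T * (x / yhat**2)) @ g
    cov_free = np.linalg.inv(info)
    if dispersion_scale:
        chi2 = float((((x - n * yhat) ** 2) / (n * yhat)).sum())
        dof = max(len(doses) - free.size, 1)
        cov_free = cov_free * max(1.0, chi2 / dof)

    coef = np.zeros(3)
    cov = np.zeros((3, 3))
    coef[free] = b
    cov[np.ix_(free, free)] = cov_free
    return CalibrationCurve(
        c=float(coef[0]),
        alpha=float(coef[1]),
        beta=float(coef[2]),
        covariance=cov,
        order=order,
        loglik=_loglik(x, n, yhat),
        n_free_parameters=int(free.size),
        n_iterations=it,
    )


def predict_yield(curve: CalibrationCurve, dose):
    """Expected dicentric yield C + alpha*D + beta*D**2 at one or more doses."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise InvalidCountData("dose must be non-negative")
    y = curve.c + curve.alpha * d + curve.beta * d**2
    return float(y) if np.isscalar(dose) or d.ndim == 0 else y


def goodness_of_fit(
    curve: CalibrationCurve, table: DicentricCountTable
) -> FitDiagnostics:
    """Pearson goodness of fit and coefficient z-tests.

    ``chi2 = sum_i (X_i - N_i*Yhat_i)^2 / (N_i*Yhat_i)`` on the aggregated
    per-dose counts, with ``dof = #doses - #fitted coefficients`` and the
    p-value from the upper tail of chi2(dof).
    """
    doses, n, x = table.doses, table.cells.astype(float), table.dicentrics.astype(float)
    yhat = curve.c + curve.alpha * doses + curve.beta * doses**2
    if np.any(yhat <= 0):
        bad = doses[yhat <= 0][0]
        raise DegenerateFitError(f"fitted yield is non-positive at {bad} Gy")
    mu = n * yhat
    resid = (x - mu) / np.sqrt(mu)
    chi2 = float((resid**2).sum())
    dof = len(doses) - curve.n_free_parameters
    if dof <= 0:
        raise DCACalibError("no residual degrees of freedom for a fit test")
    p = float(stats.chi2.sf(chi2, dof))
    coef_z, coef_p = {}, {}
    for name, est, se in [
        ("c", curve.c, curve.se_c),
        ("alpha", curve.alpha, curve.se_alpha),
        ("beta", curve.beta, curve.se_beta),
    ]:
        if se and se > 0 and np.isfinite(se):
            z = est / se
            coef_z[name] = float(z)
            coef_p[name] = float(2 * stats.norm.sf(abs(z)))
        else:
            coef_z[name] = float("nan")
            coef_p[name] = float("nan")
    return FitDiagnostics(
        pearson_chi2=chi2,
        dof=dof,
        p_value=p,
        fitted_yields=yhat,
        pearson_residuals=resid,
        coef_z=coef_z,
        coef_p=coef_p,
    )


def curve_confidence_band(
    curve: CalibrationCurve,
    doses: Sequence[float],
    cells: Sequence[float] | None = None,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for the fitted yield curve.

    At each dose the half-width is ``z * sqrt(g' Sigma g)`` with gradient
    ``g = (1, D, D**2)`` and ``Sigma`` the coefficient covariance.  When
    ``cells`` is given, the per-dose Poisson sampling variance ``Yhat / N``
    is added inside the square root, widening the band to cover observed
    yields rather than just the curve itself.  The lower bound is clipped
    at zero.
    """
    if curve.covariance is None:
        raise DCACalibError("curve has no covariance; cannot form a confidence band")
    d = np.asarray(doses, dtype=float)
    g = np.column_stack([np.ones_like(d), d, d**2])
    var = np.einsum("ij,jk,ik->i", g, curve.covariance, g)
    yhat = curve.c + curve.alpha * d + curve.beta * d**2
    if cells is not None:
        var = var + yhat / np.asarray(cells, dtype=float)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return np.clip(yhat - half, 0.0, None), yhat + half
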