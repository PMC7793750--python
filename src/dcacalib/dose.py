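"""Inverse dose estimation against a fitted calibration curve.

Given an observed dicentric count ``X`` in ``N`` metaphases and a fitted LQ
curve ``Y(D) = C + alpha*D + beta*D**2``, the absorbed dose solves
``Y(D) = X/N`` via the positive quadratic root

    D = (-alpha + sqrt(alpha**2 + 4*beta*(Y - C))) / (2*beta)

(with the linear fallback ``D = (Y - C)/alpha`` when beta = 0).  Uncertainty
combines the Poisson error of the observed yield (``Var(Y) = Y/N``) with the
calibration-curve error (delta method through the coefficient covariance,
gradient ``(1, D, D**2)``), divided by the local slope ``alpha + 2*beta*D``:

    se_D = sqrt(Y/N + g' Sigma g) / (alpha + 2*beta*D)

95% limits are ``D +- 1.96 * se_D`` clipped at zero.  Casualties are sorted
into triage categories by the point estimate: < 2 Gy (category 1, discharge
and follow up), 2-5 Gy (category 2, admission and observation for
hematopoietic acute radiation syndrome), > 5 Gy (category 3, intensive
care).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidCountData, UndefinedStatisticError
from .lq import CalibrationCurve

__all__ = [
    "DoseEstimate",
    "estimate_dose",
    "triage_category",
    "minimum_resolvable_dose",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DoseEstimate:
    """An inverted dose with combined-error 95% limits and triage category."""

    cells: int
    dicentrics: int
    yield_: float
    se_yield_poisson: float
    dose: float
    se_dose: float
    ci95: tuple[float, float]
    below_background: bool
    above_calibration_range: bool
    triage_category: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95"] = list(self.ci95)
        return d


def _invert_yield(curve: CalibrationCurve, y: float) -> float:
    """Positive root of C + alpha*D + beta*D**2 = y (y > C assumed)."""
    dy = y - curve.c
    if curve.beta > 0:
        disc = curve.alpha**2 + 4.0 * curve.beta * dy
        return (-curve.alpha + math.sqrt(disc)) / (2.0 * curve.beta)
    if curve.alpha > 0:
        return dy / curve.alpha
    raise UndefinedStatisticError("curve has no positive dose coefficient to invert")


def estimate_dose(
    curve: CalibrationCurve,
    cells: int,
    dicentrics: int,
    max_calibrated_dose: float = 5.0,
    include_covariance: bool = True,
) -> DoseEstimate:
    """Estimate the absorbed dose from an observed dicentric count.

    Parameters
    ----------
    curve
        Fitted calibration curve (needs a covariance for the curve-error
        term; a curve built from published SEs uses a diagonal covariance).
    cells, dicentrics
        The observed metaphase and dicentric counts.
    max_calibrated_dose
        Doses above this are reported with an extrapolation flag rather
        than refused (the reference curves span 0-5 Gy).
    include_covariance
        If False, only the diagonal of the coefficient covariance enters
        the curve-error term (the variant matching reports that publish
        SEs without covariances).
    """
    if cells <= 0:
        raise InvalidCountData("cells must be positive")
    if dicentrics < 0:
        raise InvalidCountData("dicentrics must be non-negative")
    y = dicentrics / cells
    se_y_poisson = math.sqrt(dicentrics) / cells

    below = y <= curve.c
    dose = 0.0 if below else _invert_yield(curve, y)

    slope = curve.alpha + 2.0 * curve.beta * dose
    if curve.covariance is not None and slope > 0:
        g = np.array([1.0, dose, dose**2])
        cov = curve.covariance
        if not include_covariance:
            cov = np.diag(np.diag(cov))
        var_curve = float(g @ cov @ g)
        var_y = y / cells + var_curve
        se_dose = math.sqrt(var_y) / slope
    else:
        se_dose = float("nan")

    if math.isfinite(se_dose):
        lo = max(dose - Z95 * se_dose, 0.0)
        hi = dose + Z95 * se_dose
    else:
        lo = hi = float("nan")

    return DoseEstimate(
        cells=int(cells),
        dicentrics=int(dicentrics),
        yield_=y,
        se_yield_poisson=se_y_poisson,
        dose=dose,
        se_dose=se_dose,
        ci95=(lo, hi),
        below_background=bool(below),
        above_calibration_range=bool(dose > max_calibrated_dose),
        triage_category=triage_category(dose),
    )


def triage_category(estimate) -> int:
    """Triage category from a dose (Gy) or a :class:`DoseEstimate`.

    dose < 2 Gy -> 1; 2 <= dose <= 5 Gy -> 2; dose > 5 Gy -> 3.  The
    boundaries are assigned to category 2 (conservative: toward medical
    observation).
    """
    dose = estimate.dose if isinstance(estimate, DoseEstimate) else float(estimate)
    if dose < 0:
        raise InvalidCountData("dose must be non-negative")
    if dose < 2.0:
        return 1
    if dose <= 5.0:
        return 2
    return 3


def minimum_resolvable_dose(
    curve: CalibrationCurve,
    aberrations: int = 6,
    per_cells: int = 1000,
) -> float:
    """Dose whose expected yield equals ``aberrations / per_cells``.

    A conventional figure of merit for calibration-curve sensitivity: the
    dose at which the expected dicentric count over ``per_cells`` scored
    metaphases reaches the stated number of aberrations (default six per
    1,000 cells).
    """
    if aberrations <= 0 or per_cells <= 0:
        raise InvalidCountData("aberrations and per_cells must be positive")
    target = aberrations / per_cells
    if target <= curve.c:
        raise UndefinedStatisticError(
            f"background yield {curve.c:.4g} exceeds target yield {target:.4g}"
        )
    return _invert_yield(curve, target)
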