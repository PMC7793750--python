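"""Chi-squared homogeneity testing of dicentric counts across groups.

Groups (doses, volunteers, age classes, ...) are compared as Poisson totals
with the scored cell number as exposure: under the null hypothesis of a
common yield ``p = sum(X) / sum(N)``, group i is expected to contribute
``E_i = N_i * p`` dicentrics, and

    chi2 = sum_i (X_i - E_i)**2 / E_i,   dof = #groups - 1.

This is the test used to decide, for instance, whether the lowest tested
dose is distinguishable from background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InvalidCountData, UndefinedStatisticError

__all__ = ["HomogeneityResult", "homogeneity_test"]


@dataclass(frozen=True)
class HomogeneityResult:
    chi2: float
    dof: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    pooled_yield: float


def homogeneity_test(groups: Sequence[tuple[int, int]]) -> HomogeneityResult:
    """Test whether groups of (cells, dicentrics) share a common yield.

    Parameters
    ----------
    groups
        Sequence of ``(cells, dicentrics)`` pairs, one per group; at least
        two groups, all with ``cells > 0`` and at least one dicentric
        overall.

    No continuity correction is applied.
    """
    arr = np.asarray(list(groups), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidCountData("need at least two (cells, dicentrics) groups")
    n, x = arr[:, 0], arr[:, 1]
    if np.any(n <= 0):
        raise InvalidCountData("every group must have cells > 0")
    if np.any(x < 0):
        raise InvalidCountData("dicentric counts must be non-negative")
    if x.sum() == 0:
        raise UndefinedStatisticError(
            "homogeneity test undefined with zero pooled dicentrics"
        )
    pooled = x.sum() / n.sum()
    expected = n * pooled
    chi2 = float(((x - expected) ** 2 / expected).sum())
    dof = arr.shape[0] - 1
    return HomogeneityResult(
        chi2=chi2,
        dof=dof,
        p_value=float(stats.chi2.sf(chi2, dof)),
        observed=x,
        expected=expected,
        pooled_yield=float(pooled),
    )
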