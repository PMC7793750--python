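"""Dicentric count tables and per-dose descriptive statistics.

The unit of observation in the dicentric chromosome assay (DCA) is a complete
metaphase cell; at each absorbed dose a laboratory records how many metaphases
contained 0, 1, 2, ... dicentric chromosomes.  This module holds that data
model and the descriptive statistics conventionally reported with it:

* the dicentric yield ``Y = X / N`` (dicentrics per metaphase) with its
  standard error,
* the sample variance of per-cell counts and the dispersion index
  ``DI = variance / mean``, and
* Papworth's u statistic, the normalized dispersion test used to check
  compliance with the Poisson distribution (|u| <= 1.96 at the 5% level).

Rows and tables are plain containers; structural validation is centralized in
:func:`validate_table` so that readers and fitting routines can decide when to
enforce it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidCountData, UndefinedStatisticError

__all__ = [
    "DoseCountRow",
    "RowStatistics",
    "DicentricCountTable",
    "dicentric_yield",
    "dispersion_stats",
    "validate_table",
]


@dataclass(frozen=True)
class DoseCountRow:
    """Metaphase counts for one absorbed dose.

    Parameters
    ----------
    dose
        Absorbed dose in Gy (>= 0).
    cells
        Number of complete metaphases scored (N).
    multiplicity_counts
        ``D_0 .. D_kmax`` where ``D_k`` is the number of metaphases that
        contained exactly ``k`` dicentrics.  Any finite ``kmax`` is accepted;
        conventional scorers cap at 5.
    """

    dose: float
    cells: int
    multiplicity_counts: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "multiplicity_counts", tuple(int(d) for d in self.multiplicity_counts)
        )

    @property
    def total_dicentrics(self) -> int:
        """Total dicentrics X = sum_k k * D_k."""
        return int(sum(k * d for k, d in enumerate(self.multiplicity_counts)))

    @property
    def kmax(self) -> int:
        return len(self.multiplicity_counts) - 1

    def expand(self) -> np.ndarray:
        """Explicit per-cell count vector (length ``cells``).

        Mostly useful for brute-force cross-checks and resampling; the
        statistics themselves are computed from the multiplicities directly.
        """
        return np.repeat(
            np.arange(len(self.multiplicity_counts)), self.multiplicity_counts
        )


@dataclass(frozen=True)
class RowStatistics:
    """Descriptive statistics of the per-cell dicentric counts at one dose."""

    yield_: float
    se_yield: float
    sample_variance: float
    dispersion_index: float
    u_statistic: float


@dataclass(frozen=True)
class DicentricCountTable:
    """An ordered collection of :class:`DoseCountRow` with unique doses.

    ``label`` is a free-text tag for the scoring mode or radiation quality
    (e.g. ``"assisted"`` vs ``"automated"``).
    """

    rows: tuple[DoseCountRow, ...]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.rows], dtype=float)

    @property
    def cells(self) -> np.ndarray:
        return np.array([r.cells for r in self.rows], dtype=np.int64)

    @property
    def dicentrics(self) -> np.ndarray:
        return np.array([r.total_dicentrics for r in self.rows], dtype=np.int64)

    @property
    def total_cells(self) -> int:
        return int(self.cells.sum())

    @property
    def total_dicentrics(self) -> int:
        return int(self.dicentrics.sum())

    @property
    def yields(self) -> np.ndarray:
        return self.dicentrics / self.cells

    def validate(self) -> "DicentricCountTable":
        return validate_table(self)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide layout: dose_gy, n_cells, d0..dk (the on-disk format)."""
        kmax = max(r.kmax for r in self.rows)
        records = []
        for r in self.rows:
            d = list(r.multiplicity_counts) + [0] * (kmax - r.kmax)
            records.append([r.dose, r.cells, *d])
        cols = ["dose_gy", "n_cells"] + [f"d{k}" for k in range(kmax + 1)]
        return pd.DataFrame(records, columns=cols)

    def statistics(self) -> pd.DataFrame:
        """Per-dose Y, SE, variance, DI and u for every row (full precision)."""
        recs = []
        for r in self.rows:
            y, se = dicentric_yield(r)
            if r.total_dicentrics > 0 and r.cells > 1:
                s = dispersion_stats(r)
                var, di, u = s.sample_variance, s.dispersion_index, s.u_statistic
            else:
                var, di, u = (math.nan,) * 3
            recs.append(
                dict(
                    dose_gy=r.dose,
                    n_cells=r.cells,
                    dicentrics=r.total_dicentrics,
                    yield_=y,
                    se_yield=se,
                    variance=var,
                    dispersion_index=di,
                    u_statistic=u,
                )
            )
        return pd.DataFrame.from_records(recs)


def _check_row(row: DoseCountRow, index: int) -> None:
    where = f"row {index} (dose {row.dose} Gy)"
    if row.dose < 0:
        raise InvalidCountData(f"{where}: negative dose")
    if not float(row.cells).is_integer() or row.cells <= 0:
        raise InvalidCountData(f"{where}: cells must be a positive integer")
    for k, d in enumerate(row.multiplicity_counts):
        if d < 0:
            raise InvalidCountData(f"{where}: negative count d{k} = {d}")
    total = sum(row.multiplicity_counts)
    if total != row.cells:
        raise InvalidCountData(
            f"{where}: multiplicity counts sum to {total}, expected cells = {row.cells}"
        )


def validate_table(table: DicentricCountTable) -> DicentricCountTable:
    """Check structural invariants, returning the table unchanged if valid.

    Every row must satisfy ``sum_k D_k = cells`` with non-negative integer
    counts, and doses must be unique and strictly ascending.  The first
    offending row is named in the raised :class:`InvalidCountData`.
    """
    if len(table.rows) == 0:
        raise InvalidCountData("table has no rows")
    for i, row in enumerate(table.rows):
        _check_row(row, i)
    doses = table.doses
    if np.any(np.diff(doses) <= 0):
        j = int(np.flatnonzero(np.diff(doses) <= 0)[0]) + 1
        raise InvalidCountData(
            f"row {j}: doses must be unique and ascending (got {doses[j]} after {doses[j - 1]})"
        )
    return table


def _raw_moments(row: DoseCountRow) -> tuple[int, int, float, float]:
    """(X, N, mean, sample variance with divisor N-1)."""
    k = np.arange(len(row.multiplicity_counts))
    d = np.asarray(row.multiplicity_counts)
    n = row.cells
    x = int((k * d).sum())
    mean = x / n
    variance = float(((k**2 * d).sum() - n * mean**2) / (n - 1)) if n > 1 else math.nan
    return x, n, mean, variance


def dicentric_yield(row: DoseCountRow) -> tuple[float, float]:
    """Dicentric yield Y = X/N and its standard error.

    The standard error is the Poisson value ``sqrt(X)/N``; when the row is
    overdispersed (DI > 1) it is inflated by ``sqrt(DI)`` — the usual
    quasi-Poisson correction.  ``SE = 0`` when no dicentrics were observed.
    """
    if row.cells <= 0:
        raise InvalidCountData("cells must be positive to compute a yield")
    x, n, mean, variance = _raw_moments(row)
    if x == 0:
        return 0.0, 0.0
    se = math.sqrt(x) / n
    if n > 1 and mean > 0:
        di = variance / mean
        if di > 1:
            se = math.sqrt(di * x) / n
    return mean, se


def dispersion_stats(row: DoseCountRow) -> RowStatistics:
    """Sample variance, dispersion index and Papworth's u for one dose.

    ``u = (DI - 1) * sqrt((N - 1) / (2 * (1 - 1/X)))``; values outside
    +-1.96 flag significant departure from the Poisson distribution at the
    5% level.  Undefined when the row holds no dicentrics.
    """
    if row.cells <= 1:
        raise UndefinedStatisticError(
            f"dispersion statistics need at least 2 cells (dose {row.dose} Gy)"
        )
    x, n, mean, variance = _raw_moments(row)
    if x == 0:
        raise UndefinedStatisticError(
            f"dispersion statistics undefined with zero dicentrics (dose {row.dose} Gy)"
        )
    di = variance / mean
    if x == 1:
        # 1 - 1/X vanishes; DI is identically 1 and u carries no information.
        u = math.nan
    else:
        u = (di - 1.0) * math.sqrt((n - 1) / (2.0 * (1.0 - 1.0 / x)))
    y, se = dicentric_yield(row)
    return RowStatistics(
        yield_=y,
        se_yield=se,
        sample_variance=variance,
        dispersion_index=di,
        u_statistic=u,
    )


def table_from_arrays(
    doses: Sequence[float],
    cells: Sequence[int],
    multiplicities: Iterable[Sequence[int]],
    label: str = "",
) -> DicentricCountTable:
    """Convenience constructor from parallel sequences (validated)."""
    rows = tuple(
        DoseCountRow(float(d), int(n), tuple(m))
        for d, n, m in zip(doses, cells, multiplicities)
    )
    return validate_table(DicentricCountTable(rows=rows, label=label))
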