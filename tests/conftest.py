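import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dcacalib import CalibrationCurve, load_table1_assisted, load_table2_automated

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """Pooled assisted-scoring reference counts (10 doses, 0-5 Gy)."""
    return load_table1_assisted()


@pytest.fixture(scope="session")
def table2():
    """Pooled automated-scoring counts from the same slides."""
    return load_table2_automated()


@pytest.fixture(scope="session")
def published_assisted_curve():
    """The published assisted-scoring curve: coefficients and SEs as printed."""
    return CalibrationCurve.from_coefficients(
        0.0020, 0.0369, 0.0689, se_c=0.0002, se_alpha=0.0019, se_beta=0.0009
    )


@pytest.fixture(scope="session")
def published_preliminary_curve():
    """The earlier four-donor preliminary curve, as printed."""
    return CalibrationCurve.from_coefficients(
        0.0017, 0.0260, 0.0807, se_c=0.0004, se_alpha=0.0046, se_beta=0.0024
    )


# Published per-dose statistics columns (Y, SE, DI, u), used to check that the
# descriptive statistics reproduce the reference tables at printed precision.
PRINTED_STATS_ASSISTED = {
    "dose": [0, 0.1, 0.25, 0.5, 0.75, 1, 2, 3, 4, 5],
    "Y": [0.002, 0.006, 0.016, 0.038, 0.065, 0.108, 0.348, 0.744, 1.235, 1.908],
    "SE": [0.000, 0.001, 0.001, 0.002, 0.002, 0.003, 0.007, 0.011, 0.017, 0.025],
    "DI": [1.00, 0.99, 1.00, 1.00, 0.99, 1.01, 1.00, 0.99, 1.00, 0.97],
    "U": [-0.27, -0.71, -0.33, 0.30, -0.59, 0.57, 0.28, -0.27, 0.11, -1.04],
}
PRINTED_STATS_AUTOMATED = {
    "dose": [0, 0.1, 0.25, 0.5, 0.75, 1, 2, 3, 4, 5],
    "Y": [0.056, 0.080, 0.080, 0.100, 0.129, 0.150, 0.265, 0.406, 0.616, 0.893],
    "SE": [0.001, 0.002, 0.002, 0.002, 0.003, 0.003, 0.005, 0.008, 0.010, 0.015],
    "DI": [0.98, 1.02, 1.02, 1.03, 1.01, 1.03, 1.03, 1.00, 0.98, 1.03],
    "U": [-3.08, 1.90, 2.35, 3.14, 1.35, 2.40, 2.39, 0.12, -1.04, 1.48],
}


@pytest.fixture(scope="session")
def printed_stats():
    return {"assisted": PRINTED_STATS_ASSISTED, "automated": PRINTED_STATS_AUTOMATED}


def brute_force_row_stats(row):
    """Oracle: expand multiplicities to per-cell counts, use numpy moments."""
    cells = np.repeat(np.arange(len(row.multiplicity_counts)), row.multiplicity_counts)
    n, x = cells.size, int(cells.sum())
    mean = cells.mean()
    var = cells.var(ddof=1)
    di = var / mean
    u = (di - 1) * np.sqrt((n - 1) / (2 * (1 - 1 / x))) if x > 1 else np.nan
    return mean, var, di, u
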