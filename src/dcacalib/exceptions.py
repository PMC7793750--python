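"""Exception hierarchy for dcacalib.

All package-specific errors derive from :class:`DCACalibError` so callers can
catch everything the library raises with a single ``except`` clause.
"""

from __future__ import annotations


class DCACalibError(Exception):
    """Base class for all dcacalib errors."""


class InvalidCountData(DCACalibError, ValueError):
    """A count table (or row) violates a structural invariant."""


class CountTableParseError(InvalidCountData):
    """A delimited count-table file could not be parsed.

    Carries the 1-based file line number of the first offending record when
    it is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedStatisticError(DCACalibError):
    """A requested statistic is undefined for the given data.

    Examples: the dispersion test with zero dicentrics, a homogeneity test
    with no pooled events, or a minimum resolvable dose below background.
    """


class FitConvergenceError(DCACalibError):
    """The iteratively reweighted least-squares fit failed to converge.

    ``trace`` holds the coefficient iterates for diagnosis.
    """

    def __init__(self, message: str, trace: list | None = None):
        self.trace = trace or []
        super().__init__(message)


class DegenerateFitError(DCACalibError):
    """A fitted curve predicts a non-positive yield where counts exist."""


class PipelineError(DCACalibError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
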