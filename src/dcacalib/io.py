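"""Reading and writing count tables, bundled reference data, and the pipeline.

The on-disk count-table format is a delimited (tab or comma) file with a
header ``dose_gy, n_cells, d0, d1, ..., dk`` and one row per dose, where
``dk`` is the number of metaphases containing exactly k dicentrics.
Thousands separators are accepted on input; writers emit plain integers and
exactly the multiplicity columns present.

Two reference tables from a published 320 kVp X-ray calibration study of 10
donors are bundled with the package: the pooled counts from assisted
(human-verified) scoring and from fully automated scoring of the same
slides.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .counts import DicentricCountTable, DoseCountRow, validate_table
from .dose import estimate_dose
from .exceptions import (
    CountTableParseError,
    DCACalibError,
    InvalidCountData,
    PipelineError,
)
from .lq import curve_confidence_band, fit_lq, goodness_of_fit

__all__ = [
    "read_count_table",
    "write_count_table",
    "load_table1_assisted",
    "load_table2_automated",
    "AnalysisConfig",
    "run_pipeline",
]


def read_count_table(path, label: str | None = None) -> DicentricCountTable:
    """Parse and validate a delimited count table.

    Raises :class:`CountTableParseError` naming the 1-based file line of the
    first offending record (the header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise CountTableParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", thousands=",")
    except Exception as err:  # pandas raises several parser error types
        raise CountTableParseError(f"cannot parse {path}: {err}") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"dose_gy", "n_cells"}
    if not required.issubset(df.columns):
        missing = sorted(required - set(df.columns))
        raise CountTableParseError(f"missing required column(s): {', '.join(missing)}")
    dcols = sorted(
        (c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not dcols:
        raise CountTableParseError("no multiplicity columns (d0, d1, ...) found")
    if [int(c[1:]) for c in dcols] != list(range(len(dcols))):
        raise CountTableParseError("multiplicity columns must be contiguous from d0")

    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        rec = rec._asdict()
        try:
            mult = []
            for c in dcols:
                v = rec[c]
                if pd.isna(v) or float(v) != int(float(v)):
                    raise InvalidCountData(f"non-integer count in column {c}: {v!r}")
                mult.append(int(float(v)))
            n = rec["n_cells"]
            if pd.isna(n) or float(n) != int(float(n)):
                raise InvalidCountData(f"non-integer cell count: {n!r}")
            row = DoseCountRow(float(rec["dose_gy"]), int(float(n)), tuple(mult))
            from .counts import _check_row

            _check_row(row, i)
        except InvalidCountData as err:
            raise CountTableParseError(str(err), line=line) from None
        rows.append(row)
    table = DicentricCountTable(tuple(rows), label=label or path.stem)
    try:
        return validate_table(table)
    except InvalidCountData as err:
        raise CountTableParseError(str(err)) from None


def write_count_table(table: DicentricCountTable, path, sep: str = "\t") -> None:
    """Write a count table in the standard delimited layout."""
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def _load_bundled(name: str, label: str) -> DicentricCountTable:
    ref = resources.files("dcacalib.data").joinpath(name)
    with resources.as_file(ref) as p:
        return read_count_table(p, label=label)


def load_table1_assisted() -> DicentricCountTable:
    """Pooled assisted-scoring reference counts (10 donors, 0-5 Gy)."""
    return _load_bundled("table1_assisted.tsv", "assisted")


def load_table2_automated() -> DicentricCountTable:
    """Pooled automated-scoring counts from the same slides."""
    return _load_bundled("table2_automated.tsv", "automated")


@dataclass
class AnalysisConfig:
    """Declarative configuration of a full calibration-curve analysis run."""

    input_path: str
    output_dir: str
    model_order: str = "linear-quadratic"
    label: str | None = None
    formats: tuple[str, ...] = ("json", "text")
    seed: int = 0
    estimate_cells: int | None = None
    estimate_dicentrics: int | None = None
    band_grid_step: float | None = None
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["formats"] = list(self.formats)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fmt(x, nd=4):
    return "nan" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}f}"


def _text_report(report: dict) -> str:
    lines = []
    lines.append(f"dcacalib analysis report ({report['label']})")
    lines.append(f"input: {report['input']}  seed: {report['seed']}")
    lines.append("")
    lines.append("Per-dose statistics")
    stats_df = pd.DataFrame(report["row_statistics"])
    lines.append(stats_df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    curve = report["curve"]
    co, se = curve["coefficients"], curve["standard_errors"]
    lines.append("Fitted curve  Y = C + alpha*D + beta*D^2")
    for name in ("c", "alpha", "beta"):
        lines.append(f"  {name:5s} = {_fmt(co[name])} +- {_fmt(se[name])}")
    gof = report["goodness_of_fit"]
    lines.append(
        f"Pearson chi2 = {gof['pearson_chi2']:.4f}  DF = {gof['dof']}  "
        f"P = {gof['p_value_text']}"
    )
    lines.append(
        "lack of fit: " + ("YES (P < 0.05)" if gof["lack_of_fit"] else "no")
    )
    if "dose_estimate" in report:
        est = report["dose_estimate"]
        lines.append("")
        lines.append(
            f"Dose estimate: {est['dicentrics']} dicentrics / {est['cells']} cells"
            f" -> {est['dose']:.4f} Gy (se {est['se_dose']:.4f}),"
            f" 95% CI [{est['ci95'][0]:.4f}, {est['ci95'][1]:.4f}],"
            f" triage category {est['triage_category']}"
        )
    lines.append("")
    return "\n".join(lines)


def _p_text(p: float, threshold: float = 1e-4) -> str:
    return f"< {threshold:g}" if p < threshold else f"{p:.4f}"


def run_pipeline(config: AnalysisConfig) -> dict:
    """Validate, summarize, fit and report on one count table.

    Stages: validate -> per-row statistics -> fit -> diagnostics ->
    (optional) dose estimate.  Writes ``report.json`` and/or ``report.txt``
    plus ``run.log`` into the output directory.  Outputs are deterministic
    (byte-identical across reruns with the same inputs and config); any
    partial outputs are removed if a stage fails.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "validate"
    try:
        table = read_count_table(config.input_path, label=config.label)

        stage = "row-statistics"
        stats_df = table.statistics()

        stage = "fit"
        curve = fit_lq(table, order=config.model_order)

        stage = "diagnostics"
        diag = goodness_of_fit(curve, table)

        report: dict = {
            "package_version": _pkg_version,
            "label": table.label,
            "input": str(config.input_path),
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "totals": {
                "cells": table.total_cells,
                "dicentrics": table.total_dicentrics,
            },
            "row_statistics": json.loads(stats_df.to_json(orient="records")),
            "curve": curve.to_dict(),
            "goodness_of_fit": {
                "pearson_chi2": diag.pearson_chi2,
                "dof": diag.dof,
                "p_value": diag.p_value,
                "p_value_text": _p_text(diag.p_value),
                "lack_of_fit": bool(diag.p_value < 0.05),
                "coef_z": diag.coef_z,
                "coef_p": diag.coef_p,
                "fitted_yields": diag.fitted_yields.tolist(),
                "observed_yields": table.yields.tolist(),
            },
        }

        if config.estimate_cells is not None and config.estimate_dicentrics is not None:
            stage = "dose-estimate"
            est = estimate_dose(curve, config.estimate_cells, config.estimate_dicentrics)
            report["dose_estimate"] = est.to_dict()

        stage = "write-reports"
        if config.band_grid_step:
            grid = np.arange(0.0, table.doses.max() + 1e-9, config.band_grid_step)
            lo, hi = curve_confidence_band(curve, grid)
            band = pd.DataFrame(
                {"dose_gy": grid, "yield": curve.predict(grid), "lower95": lo, "upper95": hi}
            )
            band_path = outdir / "band.tsv"
            band.to_csv(band_path, sep="\t", index=False)
            written.append(band_path)
        if "json" in config.formats:
            p = outdir / "report.json"
            p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            written.append(p)
        if "text" in config.formats:
            p = outdir / "report.txt"
            p.write_text(_text_report(report))
            written.append(p)
        log = outdir / "run.log"
        log.write_text(
            "\n".join(
                [
                    f"dcacalib {_pkg_version}",
                    f"python {sys.version.split()[0]} ({platform.system()})",
                    f"numpy {np.__version__}, pandas {pd.__version__}",
                    f"seed {config.seed}",
                    f"config_hash {config.config_hash()}",
                    f"stages validate,row-statistics,fit,diagnostics,write-reports",
                ]
            )
            + "\n"
        )
        written.append(log)
        return report
    except DCACalibError as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(err)) from err
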