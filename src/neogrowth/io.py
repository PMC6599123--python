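"""Cohort/chart file I/O and the end-to-end analysis pipeline.

Cohort CSV dialect: header
``id,sex,ga_days,birth_weight,discharge_weight,stay_days[,covariate...]``.
Extra columns are carried along as covariates; rows with a missing or
invalid core field are rejected with line-numbered reasons (a real
two-point cohort typically loses a fraction of records this way, and the
count is part of the report).

:func:`run_pipeline` composes the whole analysis — velocities, cohort
summary, calibration, Bland-Altman limits, tiered classification,
subgroup summaries and determinant regression — and writes a JSON report
plus a scatter CSV.  Floating-point output is rounded to 10 significant
digits so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, determinants, synthetic, velocity
from .charts import GrowthChart, SEXES, read_chart_csv, write_chart_csv

__all__ = [
    "RunConfig",
    "read_cohort",
    "write_report_json",
    "run_pipeline",
    "convert_table",
    "simulate_to_files",
]

logger = logging.getLogger(__name__)

_CORE = velocity.COHORT_CORE_COLUMNS


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    cohort_path: str | None = None
    chart_path: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    thresholds: tuple[float, float] = agreement.DEFAULT_THRESHOLDS
    on_chart_error: str = "raise"  # or "skip"
    out_dir: str | None = None
    regression_spec: determinants.RegressionSpec = field(
        default_factory=determinants.default_spec
    )

    def validate(self) -> None:
        t1, t2 = self.thresholds
        if not 0 < t1 < t2:
            raise ValueError("thresholds must satisfy 0 < t1 < t2")
        if self.synthetic is None:
            if self.cohort_path is None or self.chart_path is None:
                raise ValueError(
                    "need cohort_path and chart_path, or a synthetic config"
                )


def _parse_row(lineno: int, row: dict) -> tuple[dict | None, str | None]:
    vals = {k: (v.strip() if isinstance(v, str) else v) for k, v in row.items()}
    for col in _CORE:
        if vals.get(col) in (None, ""):
            return None, f"line {lineno}: missing {col}"
    if vals["sex"] not in SEXES:
        return None, f"line {lineno}: unknown sex {vals['sex']!r}"
    try:
        ga = int(float(vals["ga_days"]))
        w1 = float(vals["birth_weight"])
        wn = float(vals["discharge_weight"])
        stay = int(float(vals["stay_days"]))
    except ValueError:
        return None, f"line {lineno}: non-numeric core field"
    if w1 <= 0 or wn <= 0:
        return None, f"line {lineno}: weights must be positive"
    if stay < 1:
        return None, f"line {lineno}: stay_days must be >= 1"
    if not 22 * 7 <= ga < 33 * 7:
        return None, f"line {lineno}: ga_days {ga} outside [154, 231)"
    out = dict(vals)
    out.update(
        {"ga_days": ga, "birth_weight": w1, "discharge_weight": wn, "stay_days": stay}
    )
    return out, None


def read_cohort(path) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a cohort CSV.

    Returns the accepted records and the list of line-numbered rejection
    reasons (also logged).  Raises if the header is malformed or no valid
    row remains.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in _CORE if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: header missing columns {missing}")
        rows, rejections = [], []
        for lineno, row in enumerate(reader, start=2):
            parsed, why = _parse_row(lineno, row)
            if parsed is None:
                rejections.append(why)
            else:
                rows.append(parsed)
    if rejections:
        logger.warning("%s: rejected %d row(s): %s", path, len(rejections),
                       "; ".join(rejections[:5]))
    if not rows:
        raise ValueError(f"{path}: no valid cohort rows")
    frame = pd.DataFrame(rows)
    # Covariates arrive as text; make them numeric where possible.
    for col in frame.columns:
        if col in _CORE:
            continue
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError):
            pass
    return frame, rejections


def _round_sig(x: float, digits: int = 10) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def _jsonable(obj):
    """Recursively convert to JSON-safe types with 10-significant-digit floats."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if obj is None or isinstance(obj, (str, bool)):
        return obj
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return str(obj)


def write_report_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _analysis_frame(cohort: pd.DataFrame, results: pd.DataFrame,
                    d: np.ndarray) -> pd.DataFrame:
    frame = cohort.merge(results, on="id", validate="one_to_one")
    frame["diff"] = d
    frame["ga_stratum"] = velocity.ga_stratum(frame["ga_days"])
    frame["bwz_stratum"] = velocity.bwz_stratum(frame["z_birth"])
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """Run the full comparison analysis; optionally write report files.

    When ``config.out_dir`` is set, writes ``report.json`` and
    ``scatter.csv`` (one row per infant: id, em, predicted_em, diff,
    class).  Returns the report dict either way.
    """
    config.validate()
    if config.synthetic is not None:
        chart = synthetic.generate_chart(config.synthetic)
        cohort = synthetic.generate_cohort(config.synthetic, chart)
        rejections: list[str] = []
        source = {"mode": "synthetic", "config": config.synthetic.to_dict()}
    else:
        chart = read_chart_csv(config.chart_path)
        cohort, rejections = read_cohort(config.cohort_path)
        source = {
            "mode": "files",
            "cohort_path": str(config.cohort_path),
            "chart_path": str(config.chart_path),
        }

    results = velocity.cohort_velocities(cohort, chart, config.on_chart_error)
    cohort = cohort[cohort["id"].isin(results["id"])].reset_index(drop=True)
    summary = velocity.cohort_summary(cohort, results)
    report_obj = agreement.agreement_report(results, config.thresholds)
    frame = _analysis_frame(cohort, results, report_obj.differences)

    subgroups = {
        key: agreement.subgroup_differences(frame["diff"], frame[key]).to_dict(
            orient="records"
        )
        for key in ("sex", "ga_stratum", "bwz_stratum")
    }
    det = determinants.determinants_report(frame, config.regression_spec)

    report = {
        "source": source,
        "rejected_rows": {"n": len(rejections), "reasons": rejections},
        "summary": summary,
        "agreement": report_obj.to_dict(),
        "subgroups": subgroups,
        "determinants": det,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report_json(report, out / "report.json")
        scatter = agreement.scatter_export(results, report_obj.fit, config.thresholds)
        scatter.to_csv(out / "scatter.csv", index=False, float_format="%.10g")
    return report


def simulate_to_files(config: synthetic.SyntheticConfig, out_dir) -> dict[str, Path]:
    """Write chart CSV, cohort CSV and a provenance JSON for a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chart = synthetic.generate_chart(config)
    cohort = synthetic.generate_cohort(config, chart)
    paths = {
        "chart": out / "chart.csv",
        "cohort": out / "cohort.csv",
        "provenance": out / "provenance.json",
    }
    write_chart_csv(chart, paths["chart"])
    cohort.to_csv(paths["cohort"], index=False, float_format="%.10g")
    with open(paths["provenance"], "w", encoding="utf-8") as fh:
        fh.write(config.to_json())
        fh.write("\n")
    return paths


def convert_table(path, column_map: dict[str, str], out_path=None) -> pd.DataFrame:
    """Convert a spreadsheet/CSV export into the cohort CSV dialect.

    ``column_map`` maps source column names to cohort column names and
    must cover the six core fields.  Excel input is read via pandas
    (.xlsx; legacy .xls workbooks must be re-saved first).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    missing_src = [c for c in column_map if c not in raw.columns]
    if missing_src:
        raise ValueError(f"{path}: source columns not found: {missing_src}")
    frame = raw[list(column_map)].rename(columns=column_map)
    missing_core = [c for c in _CORE if c not in frame.columns]
    if missing_core:
        raise ValueError(f"column map does not cover core fields: {missing_core}")
    if out_path is not None:
        frame.to_csv(out_path, index=False)
    return frame
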