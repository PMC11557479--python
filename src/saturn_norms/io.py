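"""Reading cohorts and configs; writing samples and normative reports.

CSV dialect is fixed (comma-separated, UTF-8, header row, decimal point) to
avoid locale ambiguity.  The report writer emits one machine-readable JSON
file at full precision plus five human-readable tables — descriptives,
regression summaries, correction formulas, Equivalent-Score tables and
correction grids — rounded for display only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from ._util import logger, round_half_up
from .adjustment import CorrectionGrid, CorrectionModel, formula_text
from .core import (
    Band,
    MeasureSpec,
    NormativeSample,
    Polarity,
    Sex,
    StudyConfig,
    SubjectRecord,
    band_label,
    default_saturn_catalog,
)
from .equivalent import EquivalentScoreTable
from .pipeline import Descriptives, MeasureResult, NormativeReport
from .tolerance import ToleranceLimits

__all__ = [
    "read_sample_csv",
    "write_sample_csv",
    "load_study_config",
    "write_report",
    "report_to_dict",
    "report_from_dict",
]

_DEMOGRAPHIC_COLS = {"subject_id", "sex", "age", "education"}
_OPTIONAL_COLS = {"mmse_adjusted", "moca_adjusted", "assisted"}


def read_sample_csv(
    path: Union[str, Path],
    catalog: Optional[Sequence[MeasureSpec]] = None,
) -> NormativeSample:
    """Load and validate a subject-level CSV into a normative sample.

    Rows with 0 years of formal education are excluded (with a logged
    reason), mirroring the normative study's exclusion rule; unknown measure
    columns are ignored with a warning; missing cells stay missing.
    """
    catalog = tuple(catalog) if catalog is not None else default_saturn_catalog()
    path = Path(path)
    df = pd.read_csv(path)
    missing = _DEMOGRAPHIC_COLS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    known = {m.measure_id for m in catalog}
    measure_cols = [c for c in df.columns if c in known]
    if not measure_cols:
        raise ValueError(f"{path}: no catalog measure columns present")
    unknown = set(df.columns) - _DEMOGRAPHIC_COLS - _OPTIONAL_COLS - known
    for col in sorted(unknown):
        logger.warning("%s: ignoring unknown column %r", path, col)

    records = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header
        try:
            education = float(row["education"])
            if education == 0:
                logger.info(
                    "%s row %d (%s): excluded, 0 years of formal education",
                    path,
                    rowno,
                    row["subject_id"],
                )
                continue
            measures = {}
            for col in measure_cols:
                value = row[col]
                if pd.notna(value):
                    measures[col] = float(value)
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    sex=Sex.parse(row["sex"]),
                    age=float(row["age"]),
                    education=education,
                    measures=measures,
                    mmse_adjusted=_opt_float(row, "mmse_adjusted"),
                    moca_adjusted=_opt_float(row, "moca_adjusted"),
                    assisted=_opt_bool(row, "assisted"),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path} row {rowno}: {exc}") from exc
    return NormativeSample(records=tuple(records), catalog=catalog)


def _opt_float(row, col: str) -> Optional[float]:
    if col in row.index and pd.notna(row[col]):
        return float(row[col])
    return None


def _opt_bool(row, col: str) -> Optional[bool]:
    if col in row.index and pd.notna(row[col]):
        v = row[col]
        if isinstance(v, str):
            return v.strip().lower() in {"1", "true", "yes", "y"}
        return bool(v)
    return None


def write_sample_csv(sample: NormativeSample, path: Union[str, Path]) -> Path:
    path = Path(path)
    measure_ids = [m.measure_id for m in sample.catalog]
    rows = []
    for r in sample.records:
        row: dict = {
            "subject_id": r.subject_id,
            "sex": r.sex.value,
            "age": r.age,
            "education": r.education,
        }
        for mid in measure_ids:
            row[mid] = r.measures.get(mid)
        if r.mmse_adjusted is not None:
            row["mmse_adjusted"] = r.mmse_adjusted
        if r.moca_adjusted is not None:
            row["moca_adjusted"] = r.moca_adjusted
        if r.assisted is not None:
            row["assisted"] = int(r.assisted)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_study_config(path: Union[str, Path]) -> StudyConfig:
    """StudyConfig from a YAML mapping; absent keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("age_bands", "education_bands"):
        if key in raw:
            raw[key] = tuple(tuple(b) for b in raw[key])
    return StudyConfig(**raw)


# ---------------------------------------------------------------------------
# Report serialization

def _band(b) -> list:
    return [float(b[0]), float(b[1])]


def _limits_dict(t: Optional[ToleranceLimits]) -> Optional[dict]:
    if t is None:
        return None
    d = dataclasses.asdict(t)
    d["polarity"] = t.polarity.value
    return d


def _limits_from(d: Optional[dict]) -> Optional[ToleranceLimits]:
    if d is None:
        return None
    d = dict(d)
    d["polarity"] = Polarity(d["polarity"])
    return ToleranceLimits(**d)


def _model_dict(m: Optional[CorrectionModel]) -> Optional[dict]:
    if m is None:
        return None
    return {
        "measure_id": m.measure_id,
        "intercept": m.intercept,
        "b_sex": m.b_sex,
        "b_age": m.b_age,
        "b_educ": m.b_educ,
        "p_sex": m.p_sex,
        "p_age": m.p_age,
        "p_educ": m.p_educ,
        "significant": sorted(m.significant),
        "c_age": m.c_age,
        "c_educ": m.c_educ,
        "fit_stats": list(m.fit_stats) if m.fit_stats else None,
        "extras": {k: list(v) for k, v in m.extras.items()},
    }


def _model_from(d: Optional[dict]) -> Optional[CorrectionModel]:
    if d is None:
        return None
    return CorrectionModel(
        measure_id=d["measure_id"],
        intercept=d["intercept"],
        b_sex=d["b_sex"],
        b_age=d["b_age"],
        b_educ=d["b_educ"],
        p_sex=d["p_sex"],
        p_age=d["p_age"],
        p_educ=d["p_educ"],
        significant=frozenset(d["significant"]),
        c_age=d["c_age"],
        c_educ=d["c_educ"],
        fit_stats=tuple(d["fit_stats"]) if d["fit_stats"] else None,
        extras={k: tuple(v) for k, v in d["extras"].items()},
    )


def _es_dict(t: Optional[EquivalentScoreTable]) -> Optional[dict]:
    if t is None:
        return None
    return {
        "measure_id": t.measure_id,
        "polarity": t.polarity.value,
        "n": t.n,
        "boundaries": list(t.boundaries) if t.boundaries else None,
        "cumulative_ranks": list(t.cumulative_ranks) if t.cumulative_ranks else None,
        "densities": list(t.densities) if t.densities else None,
        "ceiling": t.ceiling,
    }


def _es_from(d: Optional[dict]) -> Optional[EquivalentScoreTable]:
    if d is None:
        return None
    return EquivalentScoreTable(
        measure_id=d["measure_id"],
        polarity=Polarity(d["polarity"]),
        n=d["n"],
        boundaries=tuple(d["boundaries"]) if d["boundaries"] else None,
        cumulative_ranks=(
            tuple(d["cumulative_ranks"]) if d["cumulative_ranks"] else None
        ),
        densities=tuple(d["densities"]) if d["densities"] else None,
        ceiling=d["ceiling"],
    )


def _grid_dict(g: Optional[CorrectionGrid]) -> Optional[dict]:
    if g is None:
        return None
    return {
        "measure_id": g.measure_id,
        "age_bands": [_band(b) for b in g.age_bands],
        "education_bands": [_band(b) for b in g.education_bands],
        "cells": [
            {
                "age_band": _band(a),
                "education_band": _band(e),
                "correction": g.cell_corrections[(a, e)],
                "representative": list(g.representatives[(a, e)]),
            }
            for a in g.age_bands
            for e in g.education_bands
        ],
        "no_adjustment": g.no_adjustment,
    }


def _grid_from(d: Optional[dict]) -> Optional[CorrectionGrid]:
    if d is None:
        return None
    cells = {}
    reps = {}
    for c in d["cells"]:
        key = (tuple(c["age_band"]), tuple(c["education_band"]))
        cells[key] = c["correction"]
        reps[key] = tuple(c["representative"])
    return CorrectionGrid(
        measure_id=d["measure_id"],
        age_bands=tuple(tuple(b) for b in d["age_bands"]),
        education_bands=tuple(tuple(b) for b in d["education_bands"]),
        cell_corrections=cells,
        representatives=reps,
        no_adjustment=d["no_adjustment"],
    )


def report_to_dict(report: NormativeReport) -> dict:
    cfg = dataclasses.asdict(report.config)
    cfg["age_bands"] = [_band(b) for b in report.config.age_bands]
    cfg["education_bands"] = [_band(b) for b in report.config.education_bands]
    demo = dict(report.demographics)
    for key in ("age", "education"):
        if isinstance(demo.get(key), Descriptives):
            demo[key] = dataclasses.asdict(demo[key])
    return {
        "n": report.n,
        "config": cfg,
        "demographics": demo,
        "measures": {
            mid: {
                "descriptives": (
                    dataclasses.asdict(r.descriptives) if r.descriptives else None
                ),
                "model": _model_dict(r.model),
                "adjusted": list(r.adjusted) if r.adjusted is not None else None,
                "limits": _limits_dict(r.limits),
                "es_table": _es_dict(r.es_table),
                "grid": _grid_dict(r.grid),
                "skip_reasons": list(r.skip_reasons),
            }
            for mid, r in report.measures.items()
        },
        "stratified": {
            mid: {
                erow: {
                    acol: (list(cell) if cell is not None else None)
                    for acol, cell in row.items()
                }
                for erow, row in table.items()
            }
            for mid, table in report.stratified.items()
        },
        "correlations": [list(c) for c in report.correlations],
    }


def report_from_dict(d: dict) -> NormativeReport:
    cfg = dict(d["config"])
    cfg["age_bands"] = tuple(tuple(b) for b in cfg["age_bands"])
    cfg["education_bands"] = tuple(tuple(b) for b in cfg["education_bands"])
    demo = dict(d["demographics"])
    for key in ("age", "education"):
        if isinstance(demo.get(key), dict):
            demo[key] = Descriptives(**demo[key])
    measures = {
        mid: MeasureResult(
            measure_id=mid,
            descriptives=(
                Descriptives(**r["descriptives"]) if r["descriptives"] else None
            ),
            model=_model_from(r["model"]),
            adjusted=tuple(r["adjusted"]) if r["adjusted"] is not None else None,
            limits=_limits_from(r["limits"]),
            es_table=_es_from(r["es_table"]),
            grid=_grid_from(r["grid"]),
            skip_reasons=tuple(r["skip_reasons"]),
        )
        for mid, r in d["measures"].items()
    }
    stratified = {
        mid: {
            erow: {
                acol: (tuple(cell) if cell is not None else None)
                for acol, cell in row.items()
            }
            for erow, row in table.items()
        }
        for mid, table in d["stratified"].items()
    }
    return NormativeReport(
        n=d["n"],
        config=StudyConfig(**cfg),
        demographics=demo,
        measures=measures,
        stratified=stratified,
        correlations=tuple(tuple(c) for c in d["correlations"]),
    )


# ---------------------------------------------------------------------------
# Human-readable tables

def _rounded(x: Optional[float], nd: int) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return round_half_up(x, nd)


def _descriptives_table(report: NormativeReport) -> pd.DataFrame:
    nd = report.config.rounding
    rows = []
    demo = report.demographics
    for label, desc in (("Age", demo.get("age")), ("Education (years of)", demo.get("education"))):
        if isinstance(desc, Descriptives):
            rows.append(
                {
                    "Measure": label,
                    "Median": _rounded(desc.median, nd),
                    "Mean": _rounded(desc.mean, nd),
                    "St. Dev.": _rounded(desc.sd, nd),
                    "Min.": _rounded(desc.min, nd),
                    "Max.": _rounded(desc.max, nd),
                }
            )
    for mid, r in report.measures.items():
        if r.descriptives is None:
            continue
        d = r.descriptives
        rows.append(
            {
                "Measure": mid,
                "Median": _rounded(d.median, nd),
                "Mean": _rounded(d.mean, nd),
                "St. Dev.": _rounded(d.sd, nd),
                "Min.": _rounded(d.min, nd),
                "Max.": _rounded(d.max, nd),
            }
        )
    return pd.DataFrame(rows)


def _models_table(report: NormativeReport) -> pd.DataFrame:
    nd = 3
    rows = []
    for mid, r in report.measures.items():
        if r.model is None:
            continue
        m = r.model
        stats_ = m.fit_stats or (None, None, None, None)
        rows.append(
            {
                "Measure": mid,
                "R": _rounded(stats_[0], nd),
                "R2": _rounded(stats_[1], nd),
                "F": _rounded(stats_[2], nd),
                "p": _rounded(stats_[3], nd) if stats_[3] is not None else None,
                "Sex": _rounded(m.b_sex, nd) if "sex" in m.significant else "ns",
                "Age": _rounded(m.b_age, nd) if "age" in m.significant else "ns",
                "Education": (
                    _rounded(m.b_educ, nd) if "education" in m.significant else "ns"
                ),
            }
        )
    return pd.DataFrame(rows)


def _formulas_table(report: NormativeReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"Measure": mid, "Adjustment formula": report.formula(mid)}
            for mid, r in report.measures.items()
            if r.descriptives is not None
        ]
    )


def _es_tables_text(report: NormativeReport) -> str:
    nd = report.config.rounding
    blocks = []
    for mid, r in report.measures.items():
        if r.limits is None:
            continue
        lines = [mid]
        lines.append(
            f"  Outer npTL  {_rounded(r.limits.outer_value, nd)}"
            f"  (rank {r.limits.outer_rank})"
        )
        lines.append(
            f"  Inner npTL  {_rounded(r.limits.inner_value, nd)}"
            f"  (rank {r.limits.inner_rank})"
        )
        t = r.es_table
        if t is None or t.ceiling:
            lines.append("  ES: not partitioned (ceiling effect)")
        else:
            higher = t.polarity is Polarity.HIGHER_BETTER
            b = [_rounded(x, nd) for x in t.boundaries]
            intervals = [
                (f"<={b[0]} (cut-off)" if higher else f">={b[0]} (cut-off)"),
                f"{b[0]}-{b[1]}",
                f"{b[1]}-{b[2]}",
                f"{b[2]}-{b[3]}",
                (f">{b[3]}" if higher else f"<{b[3]}"),
            ]
            for level in range(5):
                lines.append(
                    f"  ES {level}: {intervals[level]:>24}"
                    f"  cum {t.cumulative_ranks[level]:>4}"
                    f"  density {t.densities[level]:>4}"
                )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def _grids_text(report: NormativeReport) -> str:
    nd = report.config.rounding
    blocks = []
    for mid, r in report.measures.items():
        if r.grid is None:
            continue
        g = r.grid
        age_labels = [band_label(a) for a in g.age_bands]
        rows = []
        for e in g.education_bands:
            row = {"Education": band_label(e, "education")}
            for a, lab in zip(g.age_bands, age_labels):
                v = g.cell_corrections[(a, e)]
                row[lab] = "/" if v is None else f"{_rounded(v, nd):+}"
            rows.append(row)
        blocks.append(mid + "\n" + pd.DataFrame(rows).to_string(index=False))
    return "\n\n".join(blocks) + "\n"


def write_report(report: NormativeReport, out_dir: Union[str, Path]) -> list[Path]:
    """JSON report (full precision) plus five display tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    json_path = out / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=1, allow_nan=True)
    paths.append(json_path)

    for name, df in (
        ("descriptives.txt", _descriptives_table(report)),
        ("models.txt", _models_table(report)),
        ("formulas.txt", _formulas_table(report)),
    ):
        p = out / name
        p.write_text(
            (df.to_string(index=False) if len(df) else "(empty)") + "\n",
            encoding="utf-8",
        )
        paths.append(p)
    p = out / "es_tables.txt"
    p.write_text(_es_tables_text(report), encoding="utf-8")
    paths.append(p)
    p = out / "grids.txt"
    p.write_text(_grids_text(report), encoding="utf-8")
    paths.append(p)
    return paths
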