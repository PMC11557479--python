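"""Published Italian SATURN norms (cohort of 323, ages 50-80) and
subject-level scoring against them.

The constants below transcribe the published normative study of the Italian
SATURN: per-measure regression summaries and correction formulas, outer and
inner tolerance-limit values on the adjusted-score scale, Equivalent-Score
interval boundaries, and the printed age x education correction grids
(lookup-only, since the representative demographics behind each printed cell
are not recoverable).  ``load_published_norms`` revalidates internal
consistency at load time so transcription drift cannot pass silently.

Also houses task-level aggregation: the test has 19 tasks grouped into seven
subdomains; a subdomain score is the mean of its task accuracies (or times),
the totals are the sums over all 19 tasks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._util import logger
from .adjustment import CorrectionModel, adjust_score, formula_text
from .core import (
    ACCURACY_TASK_COUNTS,
    Band,
    Polarity,
    Sex,
    SubjectRecord,
    default_saturn_catalog,
)
from .equivalent import (
    CeilingEffectError,
    EquivalentScoreTable,
    assign_es,
    es_rank_thresholds,
)
from .tolerance import ToleranceLimits, tolerance_ranks

__all__ = [
    "PublishedNorms",
    "TaskScorecard",
    "SubjectResult",
    "MeasureResultRow",
    "load_published_norms",
    "score_subject",
    "aggregate_tasks",
    "DEFAULT_TASK_MAP",
    "DEFAULT_TASK_MAXIMA",
    "CENTER_AGE",
    "CENTER_EDUC",
]

NORMS_ID = "saturn_it_2024"
NORMS_N = 323

#: normative-sample means used as centering constants in every formula
CENTER_AGE = 61.334
CENTER_EDUC = 11.316

# --- regression constants ---------------------------------------------------
# measure: (R, R2, F, p_model, b_sex, b_age, b_educ, significant set)
# Non-significant coefficients were not published; they are stored as 0 and
# excluded from `significant`, which is what drives the correction.
_MODELS: dict[str, tuple] = {
    "total_accuracy": (0.256, 0.065, 7.436, 0.001, 0.0, -0.062, 0.106, {"age", "education"}),
    "attention_accuracy": (0.104, 0.011, 1.164, None, 0.0, 0.0, 0.0, set()),
    "incidental_memory_accuracy": (0.169, 0.029, 3.123, 0.026, 0.0, -0.003, 0.0, {"age"}),
    "orientation_accuracy": (0.252, 0.063, 7.189, 0.001, 0.0, 0.0, -0.008, {"education"}),
    "recall_accuracy": (0.301, 0.091, 10.608, 0.001, 0.0, -0.028, 0.046, {"age", "education"}),
    "math_accuracy": (0.157, 0.025, 2.703, 0.046, -0.105, 0.0, 0.0, {"sex"}),
    "visuoconstructional_accuracy": (0.310, 0.096, 11.286, 0.001, 0.0, -0.003, 0.013, {"age", "education"}),
    "executive_accuracy": (0.127, 0.016, 1.755, None, 0.0, -0.005, 0.0, {"age"}),
    "total_time": (0.182, 0.033, 3.655, 0.013, 68.421, 0.0, 0.0, {"sex"}),
    "attention_time": (0.178, 0.032, 3.486, 0.016, 0.0, 0.0, -0.151, {"education"}),
    "incidental_memory_time": (0.165, 0.027, 2.964, 0.032, 0.0, 0.0, 0.0, set()),
    "orientation_time": (0.159, 0.025, 2.758, 0.042, 0.0, 0.0, -0.149, {"education"}),
    "recall_time": (0.079, 0.006, 0.664, None, 0.0, 0.0, 0.0, set()),
    "math_time": (0.221, 0.049, 5.455, 0.001, 7.738, 0.0, 0.0, {"sex"}),
    "visuoconstructional_time": (0.229, 0.052, 5.879, 0.001, 6.496, 0.0, 0.0, {"sex"}),
    "executive_time": (0.183, 0.034, 3.704, 0.012, 3.069, 0.216, 0.0, {"sex", "age"}),
    "reading_time": (0.125, 0.016, 1.685, 0.170, 0.0, 0.0, 0.0, set()),
}

#: expected rendering of each correction formula; checked at load time
_FORMULAS = {
    "total_accuracy": "Raw + [(-0.106 × (educ - 11.316)) + (0.062 × (age - 61.334))]",
    "attention_accuracy": "No adjustment",
    "incidental_memory_accuracy": "Raw + [(0.003 × (age - 61.334))]",
    "orientation_accuracy": "Raw + [(0.008 × (educ - 11.316))]",
    "recall_accuracy": "Raw + [(-0.046 × (educ - 11.316)) + (0.028 × (age - 61.334))]",
    "math_accuracy": "If female: Raw + 0.11",
    "visuoconstructional_accuracy": "Raw + [(-0.013 × (educ - 11.316)) + (0.003 × (age - 61.334))]",
    "executive_accuracy": "Raw + [(0.005 × (age - 61.334))]",
    "total_time": "If female: Raw - 68.42",
    "attention_time": "Raw + [(0.151 × (educ - 11.316))]",
    "incidental_memory_time": "No adjustment",
    "orientation_time": "Raw + [(0.149 × (educ - 11.316))]",
    "recall_time": "No adjustment",
    "math_time": "If female: Raw - 7.74",
    "visuoconstructional_time": "If female: Raw - 6.50",
    "executive_time": "Raw + [(-0.216 × (age - 61.334))] + (if female)(-3.07)",
    "reading_time": "No adjustment",
}

# --- tolerance limits and ES boundaries (adjusted-score units) --------------
# measure: (outer value, inner value)
_LIMITS: dict[str, tuple[float, float]] = {
    "total_accuracy": (16.56, 18.57),
    "attention_accuracy": (1.33, 2.00),
    "incidental_memory_accuracy": (0.36, 0.63),
    "orientation_accuracy": (0.62, 0.64),
    "recall_accuracy": (0.99, 1.39),
    "math_accuracy": (0.11, 0.50),
    "visuoconstructional_accuracy": (0.30, 0.44),
    "executive_accuracy": (0.37, 0.67),
    "total_time": (832.83, 706.56),
    "attention_time": (26.51, 18.48),
    "incidental_memory_time": (35.67, 28.57),
    "orientation_time": (16.25, 12.97),
    "recall_time": (244.64, 189.07),
    "math_time": (65.00, 42.52),
    "visuoconstructional_time": (47.73, 38.53),
    "executive_time": (61.89, 46.28),
    "reading_time": (27.59, 24.29),
}

# measure: ES boundary values at cumulative ranks (10, 36, 88, 161); None =
# ceiling effect, tolerance limits only (attention accuracy).
_ES_BOUNDARIES: dict[str, Optional[tuple[float, float, float, float]]] = {
    "total_accuracy": (16.56, 19.80, 22.40, 24.68),
    "attention_accuracy": None,
    "incidental_memory_accuracy": (0.36, 0.65, 0.69, 0.97),
    "orientation_accuracy": (0.62, 0.64, 0.68, 0.95),
    "recall_accuracy": (0.99, 1.70, 2.60, 3.19),
    "math_accuracy": (0.11, 0.61, 1.50, 1.50),
    "visuoconstructional_accuracy": (0.30, 0.48, 0.64, 0.80),
    "executive_accuracy": (0.37, 0.73, 1.29, 1.61),
    "total_time": (832.83, 662.92, 539.37, 434.49),
    "attention_time": (26.51, 16.42, 11.62, 9.66),
    "incidental_memory_time": (35.67, 24.44, 16.30, 11.02),
    "orientation_time": (16.25, 11.36, 8.27, 6.58),
    "recall_time": (244.64, 174.33, 128.91, 81.40),
    "math_time": (65.00, 36.44, 21.95, 14.79),
    "visuoconstructional_time": (47.73, 33.04, 22.00, 14.49),
    "executive_time": (61.89, 43.78, 34.93, 25.89),
    "reading_time": (27.59, 21.97, 17.72, 13.24),
}

# --- published correction grids (lookup-only) -------------------------------
_AGE_BANDS: tuple[Band, ...] = ((50, 59), (60, 69), (70, 80))
_EDUC_BANDS: tuple[Band, ...] = ((2, 8), (9, 13), (14, 30))

# rows: education <9, 9-13, >13; columns: age 50-59, 60-69, 70-80
_GRIDS: dict[str, Optional[tuple[tuple[float, float, float], ...]]] = {
    "total_accuracy": ((-0.086, 0.584, 1.413), (-0.539, 0.155, 0.703), (-1.109, -0.591, -0.007)),
    "attention_accuracy": None,
    "incidental_memory_accuracy": ((-0.022, 0.008, 0.041), (-0.022, 0.009, 0.042), (-0.021, 0.008, 0.032)),
    "orientation_accuracy": ((-0.028, -0.032, -0.042), (0.007, 0.002, 0.013), (0.051, 0.019, 0.050)),
    "recall_accuracy": ((-0.045, 0.256, 0.628), (-0.242, 0.070, 0.321), (0.103, 0.125, 0.061)),
    "math_accuracy": ((0.060, 0.057, 0.060), (0.058, 0.063, 0.044), (0.060, 0.054, 0.066)),
    "visuoconstructional_accuracy": ((0.024, 0.059, 0.110), (-0.033, 0.005, 0.021), (-0.104, -0.084, -0.050)),
    "executive_accuracy": ((-0.037, 0.013, 0.069), (-0.036, 0.015, 0.070), (-0.035, 0.013, 0.053)),
    "total_time": ((-2.27, -98.40, -220.64), (79.52, -20.67, -92.76), (182.09, 111.83, 26.58)),
    "attention_time": ((-0.54, -0.60, -0.80), (0.13, 0.04, 0.24), (0.96, 1.06, 0.95)),
    "incidental_memory_time": None,
    "orientation_time": ((-0.53, -0.59, -0.79), (0.13, 0.04, 0.24), (0.94, 1.05, 0.94)),
    "recall_time": None,
    "math_time": ((-4.42, -4.17, -4.42), (-4.24, -4.64, -3.22), (-4.39, -3.99, 4.01)),
    "visuoconstructional_time": ((-3.71, -3.50, -3.72), (-3.56, -3.90, -2.71), (-3.69, -3.35, -4.06)),
    "executive_time": ((-0.14, -2.22, -4.73), (-0.12, -2.49, -4.32), (-0.22, -2.13, -4.22)),
    "reading_time": None,
}


@dataclass(frozen=True)
class PublishedGrid:
    """Printed age x education grid, served verbatim for lookups."""

    measure_id: str
    age_bands: tuple[Band, ...]
    education_bands: tuple[Band, ...]
    cells: Optional[tuple[tuple[float, float, float], ...]]  # educ-major

    def lookup(self, age: float, education: float) -> Optional[float]:
        if self.cells is None:
            return None
        for i, e in enumerate(self.education_bands):
            for j, a in enumerate(self.age_bands):
                if a[0] <= age <= a[1] and e[0] <= education <= e[1]:
                    return self.cells[i][j]
        raise KeyError(f"no grid cell for age={age}, education={education}")


@dataclass(frozen=True)
class PublishedNorms:
    norms_id: str
    n: int
    models: Mapping[str, CorrectionModel]
    limits: Mapping[str, ToleranceLimits]
    es_tables: Mapping[str, Optional[EquivalentScoreTable]]
    grids: Mapping[str, PublishedGrid]


def load_published_norms() -> PublishedNorms:
    """Frozen published norms, consistency-checked on every load.

    Raises ``ValueError`` if the encoded regression constants stop
    reproducing the published formula text, or the ES boundaries disagree
    with the tolerance limits / rank scheme (guards transcription drift).
    """
    catalog = {m.measure_id: m for m in default_saturn_catalog()}
    outer_rank, inner_rank = tolerance_ranks(NORMS_N, 0.05, 0.95)
    thresholds = es_rank_thresholds(NORMS_N, 0.05, 0.95)
    if (outer_rank, inner_rank) != (10, 24) or thresholds != (10, 36, 88, 161, 323):
        raise ValueError("rank scheme no longer reproduces the published ranks")

    models: dict[str, CorrectionModel] = {}
    limits: dict[str, ToleranceLimits] = {}
    es_tables: dict[str, Optional[EquivalentScoreTable]] = {}
    grids: dict[str, PublishedGrid] = {}
    for mid, (r, r2, f, p, b_sex, b_age, b_educ, sig) in _MODELS.items():
        model = CorrectionModel(
            measure_id=mid,
            intercept=0.0,
            b_sex=b_sex,
            b_age=b_age,
            b_educ=b_educ,
            p_sex=None,
            p_age=None,
            p_educ=None,
            significant=frozenset(sig),
            c_age=CENTER_AGE,
            c_educ=CENTER_EDUC,
            fit_stats=(r, r2, f, p),
        )
        rendered = formula_text(model)
        if rendered != _FORMULAS[mid]:
            raise ValueError(
                f"{mid}: transcribed constants render {rendered!r}, "
                f"expected {_FORMULAS[mid]!r}"
            )
        models[mid] = model

        outer_value, inner_value = _LIMITS[mid]
        polarity = catalog[mid].polarity
        limits[mid] = ToleranceLimits(
            n=NORMS_N,
            coverage=0.05,
            confidence=0.95,
            outer_rank=outer_rank,
            inner_rank=inner_rank,
            outer_value=outer_value,
            inner_value=inner_value,
            polarity=polarity,
        )

        boundaries = _ES_BOUNDARIES[mid]
        if boundaries is None:
            es_tables[mid] = None
        else:
            if boundaries[0] != outer_value:
                raise ValueError(f"{mid}: ES0 boundary must equal the outer limit")
            es_tables[mid] = EquivalentScoreTable(
                measure_id=mid,
                polarity=polarity,
                n=NORMS_N,
                boundaries=boundaries,
                cumulative_ranks=thresholds,
                densities=(10, 26, 52, 73, 162),
            )
        grids[mid] = PublishedGrid(mid, _AGE_BANDS, _EDUC_BANDS, _GRIDS[mid])
    return PublishedNorms(
        norms_id=NORMS_ID, n=NORMS_N, models=models, limits=limits,
        es_tables=es_tables, grids=grids,
    )


# ---------------------------------------------------------------------------
# Task-level aggregation

@dataclass(frozen=True)
class TaskScorecard:
    task_id: str
    accuracy: float
    time: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.task_id}: time on task must be > 0 s")


#: subdomain -> task ids (19 tasks)
DEFAULT_TASK_MAP: dict[str, tuple[str, ...]] = {
    "attention": ("attention_g_word", "attention_fruit_words", "attention_number"),
    "incidental_memory": ("incidental_shape", "incidental_word", "incidental_number"),
    "orientation": ("orientation_month", "orientation_year", "orientation_day"),
    "recall": ("recall_five_words",),
    "math": ("math_sum", "math_difference"),
    "visuoconstructional": ("visuo_shape", "visuo_face", "visuo_line", "visuo_cube"),
    "executive": ("exec_stroop", "exec_tmt_numbers", "exec_tmt_numbers_letters"),
}

# Per-task point maxima.  Only the subdomain-mean maxima and the total of 29
# are fixed by the published scoring; the within-subdomain split below is a
# documented, configurable default consistent with both.
DEFAULT_TASK_MAXIMA: dict[str, float] = {
    "attention_g_word": 2, "attention_fruit_words": 2, "attention_number": 2,
    "incidental_shape": 1, "incidental_word": 1, "incidental_number": 1,
    "orientation_month": 1, "orientation_year": 1, "orientation_day": 1,
    "recall_five_words": 5,
    "math_sum": 1, "math_difference": 2,
    "visuo_shape": 1, "visuo_face": 1, "visuo_line": 1, "visuo_cube": 1,
    "exec_stroop": 1, "exec_tmt_numbers": 2, "exec_tmt_numbers_letters": 2,
}


def aggregate_tasks(
    cards: Sequence[TaskScorecard],
    task_map: Mapping[str, Sequence[str]] = DEFAULT_TASK_MAP,
    task_maxima: Mapping[str, float] = DEFAULT_TASK_MAXIMA,
    reading_times: Optional[Sequence[float]] = None,
) -> dict[str, float]:
    """Fold 19 task scorecards into the 17 normed measures.

    Subdomain accuracy (time) is the mean of its tasks' points (seconds);
    the totals sum over all tasks.  ``reading_times`` are the durations of
    instruction screens; their mean becomes the reading-time measure.
    """
    by_id = {c.task_id: c for c in cards}
    wanted = [t for tasks in task_map.values() for t in tasks]
    missing = [t for t in wanted if t not in by_id]
    if missing:
        raise ValueError(f"missing task scorecards: {missing}")
    for tid in wanted:
        card = by_id[tid]
        if not (0 <= card.accuracy <= task_maxima[tid]):
            raise ValueError(
                f"{tid}: accuracy {card.accuracy} outside [0, {task_maxima[tid]}]"
            )

    out: dict[str, float] = {}
    for sd, tasks in task_map.items():
        out[f"{sd}_accuracy"] = sum(by_id[t].accuracy for t in tasks) / len(tasks)
        out[f"{sd}_time"] = sum(by_id[t].time for t in tasks) / len(tasks)
    out["total_accuracy"] = sum(by_id[t].accuracy for t in wanted)
    out["total_time"] = sum(by_id[t].time for t in wanted)
    if reading_times is not None and len(reading_times):
        out["reading_time"] = float(sum(reading_times)) / len(reading_times)
    return out


# ---------------------------------------------------------------------------
# Subject-level scoring

@dataclass(frozen=True)
class MeasureResultRow:
    measure_id: str
    raw: float
    adjusted: float
    es: Optional[int]
    classification: str  # abnormal | borderline | normal


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    norms_id: str
    rows: tuple[MeasureResultRow, ...]

    def row(self, measure_id: str) -> MeasureResultRow:
        for r in self.rows:
            if r.measure_id == measure_id:
                return r
        raise KeyError(measure_id)


def classify(adjusted: float, limits: ToleranceLimits) -> str:
    """Abnormal at/beyond the outer limit, normal at/beyond the inner,
    borderline strictly in between — direction per polarity."""
    if limits.polarity is Polarity.HIGHER_BETTER:
        if adjusted <= limits.outer_value:
            return "abnormal"
        if adjusted >= limits.inner_value:
            return "normal"
    else:
        if adjusted >= limits.outer_value:
            return "abnormal"
        if adjusted <= limits.inner_value:
            return "normal"
    return "borderline"


def score_subject(record: SubjectRecord, norms: PublishedNorms) -> SubjectResult:
    """Adjusted score, ES and normality classification for every measure the
    record carries and the norms cover."""
    rows = []
    for mid, raw in record.measures.items():
        if mid not in norms.models or raw is None:
            continue
        adjusted = adjust_score(
            raw, record.sex, record.age, record.education, norms.models[mid]
        )
        table = norms.es_tables.get(mid)
        es: Optional[int] = None
        if table is not None:
            try:
                es = assign_es(adjusted, table)
            except CeilingEffectError:  # pragma: no cover - tables are pre-vetted
                es = None
        rows.append(
            MeasureResultRow(
                measure_id=mid,
                raw=raw,
                adjusted=adjusted,
                es=es,
                classification=classify(adjusted, norms.limits[mid]),
            )
        )
    if not rows:
        raise ValueError(f"{record.subject_id}: no scorable measures present")
    return SubjectResult(
        subject_id=record.subject_id, norms_id=norms.norms_id, rows=tuple(rows)
    )
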