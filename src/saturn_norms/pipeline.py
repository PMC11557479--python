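"""Orchestration of a complete normative study.

``run_study`` walks every catalog measure through the full procedure —
descriptives, the demographic regression, adjusted scores, binomial
tolerance limits, Equivalent-Score partitioning and the correction grid —
then computes the requested adjusted-score correlations.  Failures are
isolated per measure (a ceiling or an undersized subset is recorded as a
skip reason, never fatal), and the whole run is deterministic: all
randomness lives in the cohort generator.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._util import logger
from .adjustment import (
    CorrectionGrid,
    CorrectionModel,
    adjust_score,
    build_correction_grid,
    fit_correction_model,
)
from .core import (
    Band,
    NormativeSample,
    Polarity,
    Sex,
    StudyConfig,
    band_label,
)
from .equivalent import (
    ESPartitionError,
    EquivalentScoreTable,
    build_es_table,
    es_rank_thresholds,
)
from .tolerance import SampleTooSmallError, ToleranceLimits, tolerance_values

__all__ = [
    "Descriptives",
    "MeasureResult",
    "NormativeReport",
    "descriptives",
    "pearson",
    "stratified_means",
    "run_study",
]


@dataclass(frozen=True)
class Descriptives:
    n: int
    median: float
    mean: float
    sd: float
    min: float
    max: float


def descriptives(values: Sequence[float]) -> Descriptives:
    """Median (midpoint convention), mean, sample SD (n-1), min, max."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("descriptives need at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return Descriptives(
        n=int(arr.size),
        median=float(np.median(arr)),
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson product-moment r with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlation input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(len(x))


def stratified_means(
    sample: NormativeSample,
    measure_id: str,
    age_bands: Sequence[Band],
    education_bands: Sequence[Band],
) -> dict[str, dict[str, Optional[tuple[float, float, int]]]]:
    """Mean +/- SD per education-band x age-band cell, with margins.

    Keys are band labels; margins appear under "Total".  Empty cells are
    reported as None.
    """

    def _cell(records) -> Optional[tuple[float, float, int]]:
        vals = [
            r.measures[measure_id]
            for r in records
            if measure_id in r.measures and r.measures[measure_id] is not None
        ]
        if not vals:
            return None
        d = descriptives(vals)
        return (d.mean, d.sd, d.n)

    out: dict[str, dict[str, Optional[tuple[float, float, int]]]] = {}
    for e in education_bands:
        row: dict[str, Optional[tuple[float, float, int]]] = {}
        erecs = [r for r in sample.records if e[0] <= r.education <= e[1]]
        for a in age_bands:
            row[band_label(a)] = _cell(
                [r for r in erecs if a[0] <= r.age <= a[1]]
            )
        row["Total"] = _cell(erecs)
        out[band_label(e, "education")] = row
    total_row: dict[str, Optional[tuple[float, float, int]]] = {}
    for a in age_bands:
        total_row[band_label(a)] = _cell(
            [r for r in sample.records if a[0] <= r.age <= a[1]]
        )
    total_row["Total"] = _cell(list(sample.records))
    out["Total"] = total_row
    return out


@dataclass(frozen=True)
class MeasureResult:
    measure_id: str
    descriptives: Optional[Descriptives] = None
    model: Optional[CorrectionModel] = None
    adjusted: Optional[tuple[float, ...]] = None
    limits: Optional[ToleranceLimits] = None
    es_table: Optional[EquivalentScoreTable] = None
    grid: Optional[CorrectionGrid] = None
    skip_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class NormativeReport:
    n: int
    config: StudyConfig
    demographics: Mapping[str, object]
    measures: Mapping[str, MeasureResult]
    stratified: Mapping[str, Mapping[str, Mapping[str, Optional[tuple]]]]
    correlations: tuple[tuple[str, str, float, float, int], ...]

    def formula(self, measure_id: str) -> str:
        from .adjustment import formula_text

        model = self.measures[measure_id].model
        if model is None:
            return "No adjustment"
        return formula_text(model, self.config.rounding)


def _demographic_summary(sample: NormativeSample) -> dict[str, object]:
    ages = [r.age for r in sample.records]
    educ = [r.education for r in sample.records]
    n_female = sum(r.female for r in sample.records)
    assisted = [r.assisted for r in sample.records if r.assisted is not None]
    return {
        "age": descriptives(ages),
        "education": descriptives(educ),
        "n_female": n_female,
        "n_male": sample.n - n_female,
        "n_assisted": int(sum(assisted)) if assisted else None,
    }


def run_study(
    sample: NormativeSample,
    config: StudyConfig,
    correlation_pairs: Sequence[tuple[str, str]] = (
        ("total_accuracy", "mmse_adjusted"),
        ("total_accuracy", "moca_adjusted"),
        ("mmse_adjusted", "moca_adjusted"),
    ),
    extra_covariates: Optional[Sequence[str]] = None,
) -> NormativeReport:
    """Full normative study over every catalog measure.

    Correlation pairs may name measures (correlated on their adjusted
    scores) or subject attributes such as pre-adjusted MMSE/MoCA columns;
    pairs with insufficient data are skipped with a log message.
    """
    results: dict[str, MeasureResult] = {}
    stratified: dict[str, dict] = {}
    adjusted_by_measure: dict[str, dict[str, float]] = {}

    for spec in sample.catalog:
        mid = spec.measure_id
        skip: list[str] = []
        records = sample.complete_records(mid)
        if not records:
            results[mid] = MeasureResult(mid, skip_reasons=("no data",))
            continue
        values = [r.measures[mid] for r in records]
        desc = descriptives(values)
        stratified[mid] = stratified_means(
            sample, mid, config.age_bands, config.education_bands
        )

        model: Optional[CorrectionModel] = None
        adjusted: Optional[tuple[float, ...]] = None
        grid = None
        try:
            model = fit_correction_model(
                sample, mid, alpha=config.alpha, extra_covariates=extra_covariates
            )
            adjusted = tuple(
                adjust_score(r.measures[mid], r.sex, r.age, r.education, model)
                for r in records
            )
            adjusted_by_measure[mid] = {
                r.subject_id: a for r, a in zip(records, adjusted)
            }
            grid = build_correction_grid(
                model, config.age_bands, config.education_bands, sample=sample
            )
        except ValueError as exc:
            skip.append(f"model: {exc}")

        limits: Optional[ToleranceLimits] = None
        es_table: Optional[EquivalentScoreTable] = None
        if adjusted is not None:
            from .tolerance import tolerance_ranks

            try:
                ranks = tolerance_ranks(len(adjusted), config.coverage, config.confidence)
                limits = tolerance_values(
                    adjusted,
                    ranks,
                    spec.polarity,
                    coverage=config.coverage,
                    confidence=config.confidence,
                )
            except SampleTooSmallError as exc:
                skip.append(f"limits: {exc}")
            if limits is not None:
                try:
                    thresholds = es_rank_thresholds(
                        len(adjusted), config.coverage, config.confidence
                    )
                    es_table = build_es_table(
                        adjusted, spec.polarity, thresholds, measure_id=mid
                    )
                    if es_table.ceiling:
                        skip.append("es: ceiling effect; tolerance limits only")
                except ESPartitionError as exc:
                    skip.append(f"es: {exc}")

        results[mid] = MeasureResult(
            measure_id=mid,
            descriptives=desc,
            model=model,
            adjusted=adjusted,
            limits=limits,
            es_table=es_table,
            grid=grid,
            skip_reasons=tuple(skip),
        )

    correlations = []
    for a, b in correlation_pairs:
        xa = _column(sample, a, adjusted_by_measure)
        xb = _column(sample, b, adjusted_by_measure)
        common = [sid for sid in xa if sid in xb]
        if len(common) < 3:
            logger.info("correlation %s ~ %s skipped: <3 common subjects", a, b)
            continue
        try:
            r, p, n = pearson([xa[s] for s in common], [xb[s] for s in common])
        except ValueError as exc:
            logger.info("correlation %s ~ %s skipped: %s", a, b, exc)
            continue
        correlations.append((a, b, r, p, n))

    return NormativeReport(
        n=sample.n,
        config=config,
        demographics=_demographic_summary(sample),
        measures=results,
        stratified=stratified,
        correlations=tuple(correlations),
    )


def _column(
    sample: NormativeSample,
    name: str,
    adjusted_by_measure: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Adjusted scores for catalog measures; raw attribute values otherwise
    (external instruments arrive pre-adjusted)."""
    if name in adjusted_by_measure:
        return dict(adjusted_by_measure[name])
    out: dict[str, float] = {}
    for r in sample.records:
        value = getattr(r, name, None)
        if value is None:
            value = r.measures.get(name)
        if value is not None:
            out[r.subject_id] = float(value)
    return out
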