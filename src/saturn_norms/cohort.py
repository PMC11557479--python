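"""Synthetic normative cohorts with the published study's design.

The generator reproduces the study conditions of the Italian SATURN norming
cohort: 323 subjects stratified by sex x age band (50-59 / 60-69 / 70-80)
x education band (<9 / 9-13 / >13 years), with measures produced by linear
demographic effects around the published centering means plus per-measure
noise.  Accuracy measures use a Gaussian residual clipped to the score
bounds (optionally discretized to the score grid), which yields the ceiling
behaviour seen on bounded scores (attention concentrates at its maximum);
times use mean-one multiplicative lognormal noise on the linear predictor,
so values stay positive and right-skewed while OLS still recovers the
generating coefficients in expectation.

Generating defaults take the published regression coefficients as effects
and back-solve residual scales so marginal spreads approximate the study's
descriptives; those defaults are calibration targets, not ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from ._util import round_half_up
from .core import (
    Band,
    NormativeSample,
    Polarity,
    Sex,
    StudyConfig,
    SubjectRecord,
    default_saturn_catalog,
)
from .published import CENTER_AGE, CENTER_EDUC

__all__ = [
    "GeneratingModel",
    "SimulationConfig",
    "TABLE1_STRATA",
    "default_generating_models",
    "generate_demographics",
    "generate_measures",
    "make_cohort",
    "end_to_end_recovery",
]

#: (sex, age band, education band) -> count; the published 18-cell design,
#: totalling 323 (180 female / 143 male).
TABLE1_STRATA: dict[tuple[Sex, Band, Band], int] = {
    (Sex.MALE, (50, 59), (2, 8)): 27,
    (Sex.MALE, (60, 69), (2, 8)): 12,
    (Sex.MALE, (70, 80), (2, 8)): 21,
    (Sex.MALE, (50, 59), (9, 13)): 28,
    (Sex.MALE, (60, 69), (9, 13)): 14,
    (Sex.MALE, (70, 80), (9, 13)): 7,
    (Sex.MALE, (50, 59), (14, 19)): 16,
    (Sex.MALE, (60, 69), (14, 19)): 15,
    (Sex.MALE, (70, 80), (14, 19)): 3,
    (Sex.FEMALE, (50, 59), (2, 8)): 36,
    (Sex.FEMALE, (60, 69), (2, 8)): 14,
    (Sex.FEMALE, (70, 80), (2, 8)): 28,
    (Sex.FEMALE, (50, 59), (9, 13)): 34,
    (Sex.FEMALE, (60, 69), (9, 13)): 21,
    (Sex.FEMALE, (70, 80), (9, 13)): 5,
    (Sex.FEMALE, (50, 59), (14, 19)): 21,
    (Sex.FEMALE, (60, 69), (14, 19)): 16,
    (Sex.FEMALE, (70, 80), (14, 19)): 5,
}

_FEMALE_FRACTION = 180 / 323


@dataclass(frozen=True)
class GeneratingModel:
    """Linear data-generating process for one measure.

    latent = intercept + b_sex*female + b_age*(age - c_age)
             + b_educ*(educ - c_educ) + noise
    """

    b_sex: float
    b_age: float
    b_educ: float
    intercept: float
    residual_sd: float
    family: str  # gaussian-clipped | discretized | lognormal
    bounds: Optional[tuple[float, float]] = None
    grid_step: Optional[float] = None  # for the discretized family

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.family not in {"gaussian-clipped", "discretized", "lognormal"}:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family in {"gaussian-clipped", "discretized"} and self.bounds is None:
            raise ValueError("bounded families need bounds")


@dataclass(frozen=True)
class SimulationConfig:
    strata_counts: Mapping[tuple[Sex, Band, Band], int] = field(
        default_factory=lambda: dict(TABLE1_STRATA)
    )
    generating_models: Mapping[str, GeneratingModel] = field(
        default_factory=lambda: default_generating_models()
    )
    k: int = 1  # replication factor of the stratified design
    seed: int = 0
    assisted_fraction: float = 86 / 323  # assigned independently of scores

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.strata_counts.values()):
            raise ValueError("stratum counts must be >= 0")
        if self.k < 1:
            raise ValueError("replication factor k must be >= 1")


def default_generating_models() -> dict[str, GeneratingModel]:
    """Published effect structure with residual scales calibrated so the
    marginal mean/SD of each measure approximates the study descriptives."""
    catalog = {m.measure_id: m for m in default_saturn_catalog()}
    # (mean, marginal sd, b_sex, b_age, b_educ)
    accuracy = {
        "total_accuracy": (24.02, 3.1, 0.0, -0.062, 0.106),
        "attention_accuracy": (1.95, 0.20, 0.0, 0.0, 0.0),
        "incidental_memory_accuracy": (0.87, 0.19, 0.0, -0.003, 0.0),
        "orientation_accuracy": (0.84, 0.18, 0.0, 0.0, -0.008),
        "recall_accuracy": (3.22, 1.15, 0.0, -0.028, 0.046),
        "math_accuracy": (1.28, 0.45, -0.105, 0.0, 0.0),
        "visuoconstructional_accuracy": (0.78, 0.23, 0.0, -0.003, 0.013),
        "executive_accuracy": (1.38, 0.38, 0.0, -0.005, 0.0),
    }
    times = {
        "total_time": (403.09, 194.50, 68.421, 0.0, 0.0),
        "attention_time": (10.11, 5.89, 0.0, 0.0, -0.151),
        "incidental_memory_time": (13.81, 10.52, 0.0, 0.0, 0.0),
        "orientation_time": (7.37, 4.21, 0.0, 0.0, -0.149),
        "recall_time": (94.42, 65.19, 0.0, 0.0, 0.0),
        "math_time": (22.28, 19.65, 7.738, 0.0, 0.0),
        "visuoconstructional_time": (19.98, 14.60, 6.496, 0.0, 0.0),
        "executive_time": (30.11, 13.53, 3.069, 0.216, 0.0),
        "reading_time": (12.99, 7.35, 0.0, 0.0, 0.0),
    }
    models: dict[str, GeneratingModel] = {}
    for mid, (mean, sd, b_sex, b_age, b_educ) in accuracy.items():
        models[mid] = GeneratingModel(
            b_sex=b_sex,
            b_age=b_age,
            b_educ=b_educ,
            intercept=mean - b_sex * _FEMALE_FRACTION,
            residual_sd=sd,
            family="gaussian-clipped",
            bounds=catalog[mid].bounds,
        )
    for mid, (mean, sd, b_sex, b_age, b_educ) in times.items():
        models[mid] = GeneratingModel(
            b_sex=b_sex,
            b_age=b_age,
            b_educ=b_educ,
            intercept=mean - b_sex * _FEMALE_FRACTION,
            residual_sd=sd,
            family="lognormal",
        )
    return models


def _subseed(seed: int, name: str) -> np.random.Generator:
    """Stable per-stream RNG: adding a measure never perturbs the others."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def generate_demographics(
    config: SimulationConfig,
) -> list[tuple[Sex, float, float]]:
    """Exactly k x count subjects per stratum; integer ages and education
    years drawn uniformly within each band (bands inclusive)."""
    rng = _subseed(config.seed, "demographics")
    out: list[tuple[Sex, float, float]] = []
    for (sex, age_band, educ_band), count in sorted(
        config.strata_counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
    ):
        m = count * config.k
        ages = rng.integers(age_band[0], age_band[1] + 1, size=m)
        educs = rng.integers(educ_band[0], educ_band[1] + 1, size=m)
        out.extend((sex, float(a), float(e)) for a, e in zip(ages, educs))
    return out


def _measure_values(
    model: GeneratingModel,
    female: np.ndarray,
    age: np.ndarray,
    educ: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    linpred = (
        model.intercept
        + model.b_sex * female
        + model.b_age * (age - CENTER_AGE)
        + model.b_educ * (educ - CENTER_EDUC)
    )
    n = len(linpred)
    if model.family == "lognormal":
        if np.any(linpred <= 0):
            raise ValueError("lognormal family needs a positive linear predictor")
        cv = model.residual_sd / model.intercept
        sigma = math.sqrt(math.log1p(cv * cv))
        noise = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=n)
        return linpred * noise  # mean-one noise: E[value | demographics] = linpred
    values = linpred + rng.normal(0.0, model.residual_sd, size=n)
    if model.family == "discretized" and model.grid_step:
        values = np.round(values / model.grid_step) * model.grid_step
    lo, hi = model.bounds  # type: ignore[misc]
    return np.clip(values, lo, hi)


def generate_measures(
    demographics: Sequence[tuple[Sex, float, float]],
    config: SimulationConfig,
) -> NormativeSample:
    """Attach measure values (and an independent assistance flag) to the
    generated demographics, one stable random stream per measure."""
    female = np.array([1.0 if s is Sex.FEMALE else 0.0 for s, _, _ in demographics])
    age = np.array([a for _, a, _ in demographics])
    educ = np.array([e for _, _, e in demographics])

    values: dict[str, np.ndarray] = {}
    for mid, model in config.generating_models.items():
        values[mid] = _measure_values(
            model, female, age, educ, _subseed(config.seed, f"measure:{mid}")
        )
    assisted = (
        _subseed(config.seed, "assisted").random(len(demographics))
        < config.assisted_fraction
    )

    records = tuple(
        SubjectRecord(
            subject_id=f"sim{idx:05d}",
            sex=sex,
            age=a,
            education=e,
            measures={mid: float(values[mid][idx]) for mid in values},
            assisted=bool(assisted[idx]),
        )
        for idx, (sex, a, e) in enumerate(demographics)
    )
    return NormativeSample(records=records, catalog=default_saturn_catalog())


def make_cohort(config: SimulationConfig) -> NormativeSample:
    return generate_measures(generate_demographics(config), config)


def end_to_end_recovery(
    config: SimulationConfig, study_config: StudyConfig
) -> dict:
    """Generate a cohort, run the full normative pipeline on it, and report
    generating-minus-fitted coefficient gaps plus the rank structure."""
    from .pipeline import run_study  # local import to avoid a cycle

    sample = make_cohort(config)
    report = run_study(sample, study_config)
    gaps: dict[str, dict[str, float]] = {}
    fitted: dict[str, dict[str, float]] = {}
    for mid, gen in config.generating_models.items():
        res = report.measures.get(mid)
        if res is None or res.model is None:
            continue
        fitted[mid] = {
            "b_sex": res.model.b_sex,
            "b_age": res.model.b_age,
            "b_educ": res.model.b_educ,
        }
        gaps[mid] = {
            "b_sex": gen.b_sex - res.model.b_sex,
            "b_age": gen.b_age - res.model.b_age,
            "b_educ": gen.b_educ - res.model.b_educ,
        }
    any_limits = next(
        (r.limits for r in report.measures.values() if r.limits is not None), None
    )
    any_es = next(
        (
            r.es_table
            for r in report.measures.values()
            if r.es_table is not None and not r.es_table.ceiling
        ),
        None,
    )
    return {
        "n": sample.n,
        "fitted": fitted,
        "coefficient_gaps": gaps,
        "tolerance_ranks": (
            (any_limits.outer_rank, any_limits.inner_rank) if any_limits else None
        ),
        "es_cumulative_ranks": any_es.cumulative_ranks if any_es else None,
    }
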