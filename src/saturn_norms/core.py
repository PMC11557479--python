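"""Domain types and the SATURN measure catalog.

The package norms a digital cognitive screen that yields, per examinee,
accuracy points and time on task (seconds) for seven cognitive subdomains
(attention, incidental memory, temporal orientation, recall memory, math,
visuo-constructional abilities, executive functions), plus test-level totals
and an instruction reading time: 17 measures in all.  Accuracy is scored so
that higher is better; times are "lower is better".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "Sex",
    "Polarity",
    "Units",
    "MeasureSpec",
    "SubjectRecord",
    "NormativeSample",
    "StudyConfig",
    "Band",
    "default_saturn_catalog",
    "ACCURACY_TASK_COUNTS",
    "SUBDOMAINS",
    "band_label",
    "DEFAULT_AGE_BANDS",
    "DEFAULT_EDUCATION_BANDS",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, text: str) -> "Sex":
        t = str(text).strip().lower()
        if t in {"m", "male", "maschio"}:
            return cls.MALE
        if t in {"f", "female", "femmina"}:
            return cls.FEMALE
        raise ValueError(f"unrecognized sex value: {text!r}")


class Polarity(str, Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class Units(str, Enum):
    POINTS = "points"
    SECONDS = "seconds"


#: inclusive (lo, hi) in years
Band = tuple[float, float]

DEFAULT_AGE_BANDS: tuple[Band, ...] = ((50, 59), (60, 69), (70, 80))
DEFAULT_EDUCATION_BANDS: tuple[Band, ...] = ((2, 8), (9, 13), (14, 30))

_EDUC_LABELS = {(2, 8): "<9", (9, 13): "9-13", (14, 30): ">13", (14, 19): ">13"}


def band_label(band: Band, kind: str = "age") -> str:
    """Human label for a demographic band ("50-59", "<9", ">13", ...)."""
    if kind == "education" and tuple(band) in _EDUC_LABELS:
        return _EDUC_LABELS[tuple(band)]
    lo, hi = band
    return f"{lo:g}-{hi:g}"


@dataclass(frozen=True)
class MeasureSpec:
    """Static description of one normed measure."""

    measure_id: str
    label: str
    polarity: Polarity
    units: Units
    bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.units is Units.POINTS and self.bounds is None:
            raise ValueError(f"accuracy measure {self.measure_id} needs bounds")
        if self.bounds is not None and self.bounds[0] >= self.bounds[1]:
            raise ValueError(f"bad bounds for {self.measure_id}: {self.bounds}")


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: demographics plus raw measure values.

    ``measures`` maps measure_id to the raw value; a measure may simply be
    absent (missing), never stored as zero.  Adjusted scores from other
    instruments (MMSE/MoCA) are consumed pre-adjusted.
    """

    subject_id: str
    sex: Sex
    age: float
    education: float
    measures: Mapping[str, float] = field(default_factory=dict)
    mmse_adjusted: Optional[float] = None
    moca_adjusted: Optional[float] = None
    assisted: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise ValueError(f"{self.subject_id}: age must be finite and positive")
        if not (math.isfinite(self.education) and self.education > 0):
            raise ValueError(
                f"{self.subject_id}: education must be finite and > 0 years"
            )
        for mid, val in self.measures.items():
            if val is not None and not math.isfinite(val):
                raise ValueError(f"{self.subject_id}: non-finite value for {mid}")

    @property
    def female(self) -> int:
        return 1 if self.sex is Sex.FEMALE else 0


@dataclass(frozen=True)
class NormativeSample:
    """A normative cohort: validated records plus the measure catalog."""

    records: tuple[SubjectRecord, ...]
    catalog: tuple[MeasureSpec, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("a normative sample needs at least one record")
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        known = {m.measure_id for m in self.catalog}
        for r in self.records:
            unknown = set(r.measures) - known
            if unknown:
                raise ValueError(
                    f"{r.subject_id}: measures not in catalog: {sorted(unknown)}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    def spec(self, measure_id: str) -> MeasureSpec:
        for m in self.catalog:
            if m.measure_id == measure_id:
                return m
        raise KeyError(measure_id)

    def complete_records(self, measure_id: str) -> tuple[SubjectRecord, ...]:
        """Records with a non-missing value for the measure (complete-case)."""
        return tuple(
            r
            for r in self.records
            if measure_id in r.measures and r.measures[measure_id] is not None
        )


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of a normative study.

    coverage is the population tail fraction bounded by the tolerance limits
    (5% = the clinically "worst" twentieth); confidence the one-sided
    assurance of those bounds; alpha the predictor-retention threshold of the
    demographic regressions.
    """

    confidence: float = 0.95
    coverage: float = 0.05
    alpha: float = 0.05
    age_bands: tuple[Band, ...] = DEFAULT_AGE_BANDS
    education_bands: tuple[Band, ...] = DEFAULT_EDUCATION_BANDS
    rounding: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.coverage < self.confidence < 1):
            raise ValueError("require 0 < coverage < confidence < 1")
        for bands in (self.age_bands, self.education_bands):
            flat = sorted(bands)
            for (l0, h0), (l1, h1) in zip(flat, flat[1:]):
                if h0 >= l1:
                    raise ValueError(f"bands overlap or unordered: {bands}")


# ---------------------------------------------------------------------------
# Measure catalog

SUBDOMAINS = (
    "attention",
    "incidental_memory",
    "orientation",
    "recall",
    "math",
    "visuoconstructional",
    "executive",
)

#: tasks per subdomain; subdomain accuracy is the mean over its tasks
ACCURACY_TASK_COUNTS = {
    "attention": 3,
    "incidental_memory": 3,
    "orientation": 3,
    "recall": 1,
    "math": 2,
    "visuoconstructional": 4,
    "executive": 3,
}

# Maximum of the subdomain mean accuracy.  Executive is exactly 5/3 (three
# tasks worth 1+2+2 points) so that sum(max * task_count) == 29, the test's
# maximum total score; it prints as 1.67.
_ACC_MAXIMA = {
    "attention": 2.0,
    "incidental_memory": 1.0,
    "orientation": 1.0,
    "recall": 5.0,
    "math": 1.5,
    "visuoconstructional": 1.0,
    "executive": 5.0 / 3.0,
}

_LABELS = {
    "attention": "Attention",
    "incidental_memory": "Incidental memory",
    "orientation": "Orientation",
    "recall": "Recall memory",
    "math": "Math",
    "visuoconstructional": "Visuo-constructional abilities",
    "executive": "Executive functions",
}


def default_saturn_catalog() -> tuple[MeasureSpec, ...]:
    """The 17-measure SATURN catalog: total + 7 subdomain accuracies,
    total + 7 subdomain times on task, and instruction reading time."""
    specs: list[MeasureSpec] = [
        MeasureSpec(
            "total_accuracy",
            "SATURN total accuracy",
            Polarity.HIGHER_BETTER,
            Units.POINTS,
            (0.0, 29.0),
        )
    ]
    for sd in SUBDOMAINS:
        specs.append(
            MeasureSpec(
                f"{sd}_accuracy",
                f"{_LABELS[sd]} mean score",
                Polarity.HIGHER_BETTER,
                Units.POINTS,
                (0.0, _ACC_MAXIMA[sd]),
            )
        )
    specs.append(
        MeasureSpec(
            "total_time",
            "SATURN total time on tasks",
            Polarity.LOWER_BETTER,
            Units.SECONDS,
            (0.0, math.inf),
        )
    )
    for sd in SUBDOMAINS:
        specs.append(
            MeasureSpec(
                f"{sd}_time",
                f"{_LABELS[sd]} time mean score",
                Polarity.LOWER_BETTER,
                Units.SECONDS,
                (0.0, math.inf),
            )
        )
    specs.append(
        MeasureSpec(
            "reading_time",
            "Reading time mean score",
            Polarity.LOWER_BETTER,
            Units.SECONDS,
            (0.0, math.inf),
        )
    )
    return tuple(specs)
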