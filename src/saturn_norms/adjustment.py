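"""Demographic correction of raw scores by multiple linear regression.

Each measure gets one ordinary-least-squares fit of the raw score on a
female indicator (male reference), age and education in years.  The full
model's coefficients are kept at full precision; a predictor enters the
correction only if its two-sided p-value is below alpha, but the retained
coefficients are NOT refit after dropping the others.  The adjusted score
removes the estimated demographic effect around the fitting sample's means:

    adjusted = raw - sum_{j significant} b_j * (x_j - c_j)

with c_age, c_educ the sample means and c_sex = 0 (male reference), so the
correction vanishes for a male of mean age and education.  Correction grids
tabulate the same additive term at representative demographics per
age-band x education-band cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from ._util import format_half_up, logger
from .core import Band, NormativeSample, Sex, SubjectRecord, band_label

__all__ = [
    "CorrectionModel",
    "CorrectionGrid",
    "fit_correction_model",
    "adjust_score",
    "formula_text",
    "build_correction_grid",
]

PREDICTORS = ("sex", "age", "education")


@dataclass(frozen=True)
class CorrectionModel:
    """Per-measure regression summary driving score adjustment.

    p-values may be None for models loaded from published constants, where
    only the retained-predictor set is known.
    """

    measure_id: str
    intercept: float
    b_sex: float
    b_age: float
    b_educ: float
    p_sex: Optional[float]
    p_age: Optional[float]
    p_educ: Optional[float]
    significant: frozenset[str]
    c_age: float
    c_educ: float
    fit_stats: Optional[tuple[float, float, float, Optional[float]]] = None
    #: coefficient, p of any extra covariates (e.g. an assistance flag)
    extras: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.significant <= set(PREDICTORS):
            raise ValueError(f"unknown predictors in {sorted(self.significant)}")

    def coefficient(self, predictor: str) -> float:
        return {"sex": self.b_sex, "age": self.b_age, "education": self.b_educ}[
            predictor
        ]

    def centering(self, predictor: str) -> float:
        return {"sex": 0.0, "age": self.c_age, "education": self.c_educ}[predictor]


def _covariate_value(record: SubjectRecord, name: str) -> float:
    if name == "assisted":
        if record.assisted is None:
            raise ValueError(f"{record.subject_id}: assisted flag missing")
        return float(record.assisted)
    value = getattr(record, name, None)
    if value is None:
        value = record.measures.get(name)
    if value is None:
        raise ValueError(f"{record.subject_id}: covariate {name!r} missing")
    return float(value)


def fit_correction_model(
    sample: NormativeSample,
    measure_id: str,
    alpha: float = 0.05,
    extra_covariates: Optional[Sequence[str]] = None,
) -> CorrectionModel:
    """OLS of the raw measure on sex, age, education (plus extras).

    Complete-case per measure: only records with the measure present enter.
    Requires at least 10 such records and both sexes represented.
    """
    records = sample.complete_records(measure_id)
    if measure_id not in {m.measure_id for m in sample.catalog}:
        raise KeyError(f"measure {measure_id!r} not in catalog")
    if len(records) < 10:
        raise ValueError(
            f"{measure_id}: only {len(records)} complete records (need >= 10)"
        )
    sexes = {r.sex for r in records}
    if len(sexes) < 2:
        raise ValueError(f"{measure_id}: both sexes required, found {sexes}")

    extra_covariates = tuple(extra_covariates or ())
    y = np.array([r.measures[measure_id] for r in records], dtype=float)
    cols = {
        "female": np.array([r.female for r in records], dtype=float),
        "age": np.array([r.age for r in records], dtype=float),
        "education": np.array([r.education for r in records], dtype=float),
    }
    for name in extra_covariates:
        cols[name] = np.array([_covariate_value(r, name) for r in records])

    X = sm.add_constant(np.column_stack(list(cols.values())), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{measure_id}: rank-deficient design matrix")
    if np.ptp(y) == 0:
        # zero-variance response: null model, nothing significant
        return CorrectionModel(
            measure_id=measure_id,
            intercept=float(y[0]),
            b_sex=0.0,
            b_age=0.0,
            b_educ=0.0,
            p_sex=1.0,
            p_age=1.0,
            p_educ=1.0,
            significant=frozenset(),
            c_age=float(np.mean(cols["age"])),
            c_educ=float(np.mean(cols["education"])),
            fit_stats=(0.0, 0.0, 0.0, None),
            extras={n: (0.0, 1.0) for n in extra_covariates},
        )
    fit = sm.OLS(y, X).fit()

    names = ["const"] + list(cols)
    params = dict(zip(names, fit.params))
    pvals = dict(zip(names, fit.pvalues))

    def _p(name: str) -> float:
        p = pvals[name]
        return float(p) if math.isfinite(p) else 1.0  # zero-variance response

    p_by_pred = {"sex": _p("female"), "age": _p("age"), "education": _p("education")}
    significant = frozenset(p for p in PREDICTORS if p_by_pred[p] < alpha)

    f_p = float(fit.f_pvalue) if math.isfinite(fit.f_pvalue) else None
    r2 = float(fit.rsquared) if math.isfinite(fit.rsquared) else 0.0
    fstat = float(fit.fvalue) if math.isfinite(fit.fvalue) else 0.0
    return CorrectionModel(
        measure_id=measure_id,
        intercept=float(params["const"]),
        b_sex=float(params["female"]),
        b_age=float(params["age"]),
        b_educ=float(params["education"]),
        p_sex=p_by_pred["sex"],
        p_age=p_by_pred["age"],
        p_educ=p_by_pred["education"],
        significant=significant,
        c_age=float(np.mean(cols["age"])),
        c_educ=float(np.mean(cols["education"])),
        fit_stats=(math.sqrt(max(r2, 0.0)), r2, fstat, f_p),
        extras={n: (float(params[n]), _p_extra(pvals[n])) for n in extra_covariates},
    )


def _p_extra(p: float) -> float:
    return float(p) if math.isfinite(p) else 1.0


def adjust_score(
    raw: float,
    sex: Sex,
    age: float,
    education: float,
    model: CorrectionModel,
) -> float:
    """Demographically adjusted score; never clipped to the measure bounds."""
    if not (50 <= age <= 80) or not (2 <= education <= 30):
        logger.warning(
            "%s: demographics (age=%s, education=%s) outside the normative "
            "range 50-80 / 2-30 years; adjustment is an extrapolation",
            model.measure_id,
            age,
            education,
        )
    x = {"sex": 1.0 if sex is Sex.FEMALE else 0.0, "age": age, "education": education}
    correction = sum(
        model.coefficient(p) * (x[p] - model.centering(p)) for p in model.significant
    )
    return raw - correction


def formula_text(model: CorrectionModel, rounding: int = 2) -> str:
    """Human-readable correction formula in normative-table style.

    Continuous terms print the negated coefficient at three decimals around
    the centering constants; a sex effect prints as an "If female" offset at
    ``rounding`` decimals (half-up).
    """
    terms = []
    if "education" in model.significant:
        terms.append(
            f"({format_half_up(-model.b_educ, 3)} × (educ - {model.c_educ:.3f}))"
        )
    if "age" in model.significant:
        terms.append(
            f"({format_half_up(-model.b_age, 3)} × (age - {model.c_age:.3f}))"
        )
    sex_offset = None
    if "sex" in model.significant:
        sex_offset = format_half_up(-model.b_sex, rounding)

    if not terms and sex_offset is None:
        return "No adjustment"
    if not terms:
        sign = "-" if sex_offset.startswith("-") else "+"
        return f"If female: Raw {sign} {sex_offset.lstrip('-')}"
    text = f"Raw + [{' + '.join(terms)}]"
    if sex_offset is not None:
        if not sex_offset.startswith("-"):
            sex_offset = "+" + sex_offset
        text += f" + (if female)({sex_offset})"
    return text


@dataclass(frozen=True)
class CorrectionGrid:
    """Additive age x education corrections at representative demographics.

    ``cell_corrections`` maps (age_band, education_band) to the additive
    term; a model with no significant age/education effect yields a grid
    flagged ``no_adjustment`` (every cell None).  Sex is handled separately
    by the formula, as in the source tables.
    """

    measure_id: str
    age_bands: tuple[Band, ...]
    education_bands: tuple[Band, ...]
    cell_corrections: Mapping[tuple[Band, Band], Optional[float]]
    representatives: Mapping[tuple[Band, Band], tuple[float, float]]
    no_adjustment: bool = False

    def __post_init__(self) -> None:
        expected = {
            (a, e) for a in self.age_bands for e in self.education_bands
        }
        if set(self.cell_corrections) != expected:
            raise ValueError("grid must define every band pair")

    def lookup(self, age: float, education: float) -> Optional[float]:
        for a in self.age_bands:
            for e in self.education_bands:
                if a[0] <= age <= a[1] and e[0] <= education <= e[1]:
                    return self.cell_corrections[(a, e)]
        raise KeyError(f"no grid cell for age={age}, education={education}")


def _in_band(value: float, band: Band) -> bool:
    return band[0] <= value <= band[1]


def build_correction_grid(
    model: CorrectionModel,
    age_bands: Sequence[Band],
    education_bands: Sequence[Band],
    representatives: Optional[Mapping[tuple[Band, Band], tuple[float, float]]] = None,
    sample: Optional[NormativeSample] = None,
) -> CorrectionGrid:
    """Grid of additive corrections per (age band, education band) cell.

    Representative demographics per cell come, in order of preference, from
    the ``representatives`` argument, the cell means of ``sample``, or the
    band midpoints.  The cell value is ``adjust_score(0, male, ...)``: the
    additive term the formula would apply at those demographics.
    """
    age_bands = tuple(tuple(b) for b in age_bands)
    education_bands = tuple(tuple(b) for b in education_bands)
    demographic_terms = model.significant & {"age", "education"}

    reps: dict[tuple[Band, Band], tuple[float, float]] = {}
    cells: dict[tuple[Band, Band], Optional[float]] = {}
    for a in age_bands:
        for e in education_bands:
            key = (a, e)
            if representatives is not None and key in representatives:
                rep = tuple(representatives[key])
            else:
                members = (
                    [
                        r
                        for r in sample.records
                        if _in_band(r.age, a) and _in_band(r.education, e)
                    ]
                    if sample is not None
                    else []
                )
                if members:
                    rep = (
                        float(np.mean([r.age for r in members])),
                        float(np.mean([r.education for r in members])),
                    )
                else:
                    rep = ((a[0] + a[1]) / 2.0, (e[0] + e[1]) / 2.0)
                    if sample is not None:
                        logger.warning(
                            "%s: empty grid cell %s x %s; falling back to midpoints %s",
                            model.measure_id,
                            band_label(a),
                            band_label(e, "education"),
                            rep,
                        )
            reps[key] = rep
            cells[key] = (
                adjust_score(0.0, Sex.MALE, rep[0], rep[1], model)
                if demographic_terms
                else None
            )
    return CorrectionGrid(
        measure_id=model.measure_id,
        age_bands=age_bands,
        education_bands=education_bands,
        cell_corrections=cells,
        representatives=reps,
        no_adjustment=not demographic_terms,
    )
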