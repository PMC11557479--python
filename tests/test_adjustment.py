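"""Demographic regression fitting, score adjustment, formula rendering and
correction grids."""

import numpy as np
import pytest

from saturn_norms import (
    CorrectionModel,
    NormativeSample,
    Sex,
    SubjectRecord,
    adjust_score,
    build_correction_grid,
    default_saturn_catalog,
    fit_correction_model,
    formula_text,
)
from tests.conftest import make_sample

AGE_BANDS = ((50, 59), (60, 69), (70, 80))
EDUC_BANDS = ((2, 8), (9, 13), (14, 30))


def published_total_accuracy_model():
    return CorrectionModel(
        measure_id="total_accuracy",
        intercept=0.0,
        b_sex=0.0,
        b_age=-0.062,
        b_educ=0.106,
        p_sex=None,
        p_age=None,
        p_educ=None,
        significant=frozenset({"age", "education"}),
        c_age=61.334,
        c_educ=11.316,
    )


def linear_sample(n=400, seed=3, b_sex=0.0, b_age=-0.062, b_educ=0.106,
                  intercept=24.0, noise_sd=0.0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        female = i % 2
        age = float(rng.integers(50, 81))
        educ = float(rng.integers(2, 20))
        y = (
            intercept
            + b_sex * female
            + b_age * (age - 61.334)
            + b_educ * (educ - 11.316)
            + rng.normal(0, noise_sd)
        )
        records.append(
            SubjectRecord(
                subject_id=f"s{i}",
                sex=Sex.FEMALE if female else Sex.MALE,
                age=age,
                education=educ,
                measures={"total_accuracy": y},
                assisted=bool(rng.random() < 0.25),
            )
        )
    return NormativeSample(records=tuple(records), catalog=default_saturn_catalog())


def test_noiseless_fit_recovers_generating_coefficients_exactly():
    sample = linear_sample(noise_sd=0.0)
    model = fit_correction_model(sample, "total_accuracy")
    assert model.b_age == pytest.approx(-0.062, abs=1e-10)
    assert model.b_educ == pytest.approx(0.106, abs=1e-10)
    assert model.b_sex == pytest.approx(0.0, abs=1e-10)
    assert model.significant == {"age", "education"}
    assert model.fit_stats[1] == pytest.approx(1.0)


def test_constant_response_yields_null_model():
    sample = make_sample(values=[24.0] * 40)
    model = fit_correction_model(sample, "total_accuracy")
    assert model.b_age == pytest.approx(0.0, abs=1e-9)
    assert model.b_educ == pytest.approx(0.0, abs=1e-9)
    assert model.significant == frozenset()


def test_single_sex_design_rejected():
    records = tuple(
        SubjectRecord(f"s{i}", Sex.MALE, 50.0 + i, 5.0 + (i % 10),
                      {"total_accuracy": 20.0 + i % 5})
        for i in range(20)
    )
    sample = NormativeSample(records=records, catalog=default_saturn_catalog())
    with pytest.raises(ValueError, match="both sexes"):
        fit_correction_model(sample, "total_accuracy")


def test_uninformative_extra_covariate_leaves_demographics_unchanged():
    sample = linear_sample(noise_sd=1.0, seed=11)
    base = fit_correction_model(sample, "total_accuracy")
    extra = fit_correction_model(
        sample, "total_accuracy", extra_covariates=["assisted"]
    )
    # assistance assigned independently of scores: tiny numerical shifts only
    assert extra.b_age == pytest.approx(base.b_age, abs=0.01)
    assert extra.b_educ == pytest.approx(base.b_educ, abs=0.01)
    assert extra.significant == base.significant
    assert "assisted" in extra.extras


def test_adjustment_is_identity_at_centering_point():
    model = published_total_accuracy_model()
    for sex in (Sex.MALE, Sex.FEMALE):
        assert adjust_score(24.0, sex, 61.334, 11.316, model) == pytest.approx(24.0)


def test_adjustment_matches_published_formula_arithmetic():
    model = published_total_accuracy_model()
    adjusted = adjust_score(24.0, Sex.MALE, 75.0, 5.0, model)
    assert round(adjusted, 2) == 25.52


def test_female_time_offset():
    model = CorrectionModel(
        measure_id="total_time", intercept=0.0, b_sex=68.421, b_age=0.0, b_educ=0.0,
        p_sex=None, p_age=None, p_educ=None, significant=frozenset({"sex"}),
        c_age=61.334, c_educ=11.316,
    )
    assert adjust_score(500.0, Sex.FEMALE, 60.0, 10.0, model) == pytest.approx(431.579)
    assert adjust_score(500.0, Sex.MALE, 60.0, 10.0, model) == pytest.approx(500.0)


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(b_age=-0.003, significant={"age"}), "Raw + [(0.003 × (age - 61.334))]"),
        (dict(significant=set()), "No adjustment"),
        (dict(b_sex=-0.105, significant={"sex"}), "If female: Raw + 0.11"),
        (dict(b_sex=68.421, significant={"sex"}), "If female: Raw - 68.42"),
        (
            dict(b_sex=3.069, b_age=0.216, significant={"sex", "age"}),
            "Raw + [(-0.216 × (age - 61.334))] + (if female)(-3.07)",
        ),
    ],
)
def test_formula_rendering(kwargs, expected):
    base = dict(
        measure_id="m", intercept=0.0, b_sex=0.0, b_age=0.0, b_educ=0.0,
        p_sex=None, p_age=None, p_educ=None, significant=frozenset(),
        c_age=61.334, c_educ=11.316,
    )
    base.update(kwargs)
    base["significant"] = frozenset(base["significant"])
    assert formula_text(CorrectionModel(**base)) == expected


def test_grid_zero_at_centering_representative():
    model = published_total_accuracy_model()
    reps = {(a, e): (61.334, 11.316) for a in AGE_BANDS for e in EDUC_BANDS}
    grid = build_correction_grid(model, AGE_BANDS, EDUC_BANDS, representatives=reps)
    for cell in grid.cell_corrections.values():
        assert cell == pytest.approx(0.0)


def test_grid_matches_adjustment_arithmetic_bit_for_bit():
    model = published_total_accuracy_model()
    reps = {(a, e): (75.0, 5.0) for a in AGE_BANDS for e in EDUC_BANDS}
    grid = build_correction_grid(model, AGE_BANDS, EDUC_BANDS, representatives=reps)
    expected = adjust_score(0.0, Sex.MALE, 75.0, 5.0, model)
    assert round(expected, 3) == 1.517
    for (a, e), cell in grid.cell_corrections.items():
        assert cell == expected  # bit-equal by construction
        raw = 21.7
        assert adjust_score(raw, Sex.MALE, 75.0, 5.0, model) - raw == pytest.approx(
            cell, abs=1e-12
        )


def test_grid_raises_low_education_scores_when_education_helps():
    # b_educ > 0: low-education subjects get positive corrections
    model = published_total_accuracy_model()
    sample = linear_sample(noise_sd=1.0)
    grid = build_correction_grid(model, AGE_BANDS, EDUC_BANDS, sample=sample)
    low_edu_old = grid.cell_corrections[((70, 80), (2, 8))]
    high_edu_young = grid.cell_corrections[((50, 59), (14, 30))]
    assert low_edu_old > 0
    assert high_edu_young < 0


def test_null_model_grid_flags_no_adjustment():
    model = CorrectionModel(
        measure_id="reading_time", intercept=0.0, b_sex=0.0, b_age=0.0, b_educ=0.0,
        p_sex=None, p_age=None, p_educ=None, significant=frozenset(),
        c_age=61.334, c_educ=11.316,
    )
    grid = build_correction_grid(model, AGE_BANDS, EDUC_BANDS)
    assert grid.no_adjustment
    assert all(v is None for v in grid.cell_corrections.values())


def test_parameter_recovery_improves_with_sample_size():
    gaps = []
    for n in (200, 3200):
        biases = []
        for seed in range(5):
            sample = linear_sample(n=n, seed=seed, noise_sd=3.0)
            model = fit_correction_model(sample, "total_accuracy")
            biases.append(abs(model.b_educ - 0.106))
        gaps.append(np.mean(biases))
    assert gaps[1] < gaps[0]
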