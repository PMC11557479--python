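"""Catalog contents, record validation and CSV round trips."""

import math

import pytest

from saturn_norms import (
    NormativeSample,
    Polarity,
    Sex,
    SubjectRecord,
    StudyConfig,
    Units,
    default_saturn_catalog,
    read_sample_csv,
    write_sample_csv,
)
from saturn_norms.core import ACCURACY_TASK_COUNTS


def test_catalog_has_17_measures(catalog):
    assert len(catalog) == 17
    by_id = {m.measure_id: m for m in catalog}
    assert by_id["total_accuracy"].bounds == (0, 29)
    assert by_id["math_accuracy"].bounds == (0, 1.5)
    assert by_id["attention_accuracy"].bounds == (0, 2.0)
    assert by_id["recall_accuracy"].bounds == (0, 5.0)


def test_catalog_polarity_and_units(catalog):
    for m in catalog:
        if m.measure_id.endswith("_accuracy"):
            assert m.polarity is Polarity.HIGHER_BETTER
            assert m.units is Units.POINTS
            assert m.bounds is not None and m.bounds[0] == 0
        else:
            assert m.polarity is Polarity.LOWER_BETTER
            assert m.units is Units.SECONDS
            assert m.bounds[0] == 0 and math.isinf(m.bounds[1])


def test_subdomain_maxima_weighted_by_task_counts_sum_to_29(catalog):
    by_id = {m.measure_id: m for m in catalog}
    total = sum(
        by_id[f"{sd}_accuracy"].bounds[1] * count
        for sd, count in ACCURACY_TASK_COUNTS.items()
    )
    assert total == pytest.approx(29.0, abs=1e-12)


def test_zero_education_record_rejected():
    with pytest.raises(ValueError, match="education"):
        SubjectRecord("x", Sex.MALE, 60.0, 0.0, {})


def test_unknown_measure_rejected_by_sample(catalog):
    rec = SubjectRecord("x", Sex.MALE, 60.0, 8.0, {"nonsense": 1.0})
    with pytest.raises(ValueError, match="nonsense"):
        NormativeSample(records=(rec,), catalog=tuple(catalog))


def test_duplicate_subject_ids_rejected(catalog):
    rec = SubjectRecord("x", Sex.MALE, 60.0, 8.0, {"total_accuracy": 20.0})
    with pytest.raises(ValueError, match="unique"):
        NormativeSample(records=(rec, rec), catalog=tuple(catalog))


def test_config_band_overlap_rejected():
    with pytest.raises(ValueError, match="bands"):
        StudyConfig(age_bands=((50, 65), (60, 80)))
    with pytest.raises(ValueError, match="coverage"):
        StudyConfig(coverage=0.96, confidence=0.95)


def test_csv_reading_parses_sex_and_skips_zero_education(tmp_path, caplog):
    p = tmp_path / "sample.csv"
    p.write_text(
        "subject_id,sex,age,education,total_accuracy,unknown_col\n"
        "a,f,61.0,10,24.0,9\n"
        "b,MALE,70,0,20.0,9\n"
        "c,M,55,13,,9\n"
    )
    sample = read_sample_csv(p)
    assert sample.n == 2  # zero-education row excluded
    a = sample.records[0]
    assert a.sex is Sex.FEMALE and a.age == 61.0
    # missing measure cell stays missing, never zero
    assert "total_accuracy" not in sample.records[1].measures


def test_csv_malformed_row_names_position(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(
        "subject_id,sex,age,education,total_accuracy\n"
        "a,dolphin,61.0,10,24.0\n"
    )
    with pytest.raises(ValueError, match="row 2"):
        read_sample_csv(p)


def test_csv_missing_required_column(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("subject_id,sex,age,total_accuracy\na,f,61.0,24.0\n")
    with pytest.raises(ValueError, match="education"):
        read_sample_csv(p)


def test_csv_round_trip_is_lossless(tmp_path, catalog):
    records = (
        SubjectRecord(
            "a", Sex.FEMALE, 61.0, 10.0,
            {"total_accuracy": 24.25, "total_time": 403.125},
            mmse_adjusted=28.5, assisted=True,
        ),
        SubjectRecord("b", Sex.MALE, 72.0, 5.0, {"total_accuracy": 19.0}),
    )
    sample = NormativeSample(records=records, catalog=tuple(catalog))
    path = write_sample_csv(sample, tmp_path / "out.csv")
    back = read_sample_csv(path)
    for orig, loaded in zip(sample.records, back.records):
        assert loaded.subject_id == orig.subject_id
        assert loaded.sex == orig.sex
        assert loaded.age == orig.age
        assert loaded.education == orig.education
        assert loaded.measures == orig.measures
        assert loaded.mmse_adjusted == orig.mmse_adjusted
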