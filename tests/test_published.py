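"""Published-norms constants, task aggregation and subject scoring."""

import pytest

from saturn_norms import (
    Sex,
    SubjectRecord,
    TaskScorecard,
    aggregate_tasks,
    classify,
    formula_text,
    load_published_norms,
    score_subject,
)
from saturn_norms.published import DEFAULT_TASK_MAP, DEFAULT_TASK_MAXIMA


@pytest.fixture(scope="module")
def norms():
    return load_published_norms()


def test_load_is_deterministic_and_consistent(norms):
    again = load_published_norms()
    assert again.norms_id == norms.norms_id == "saturn_it_2024"
    assert again.models == norms.models
    assert again.limits == norms.limits
    assert again.es_tables == norms.es_tables


def test_total_accuracy_limits(norms):
    lim = norms.limits["total_accuracy"]
    assert (lim.outer_value, lim.inner_value) == (16.56, 18.57)
    assert (lim.outer_rank, lim.inner_rank) == (10, 24)


def test_total_time_limits(norms):
    lim = norms.limits["total_time"]
    assert (lim.outer_value, lim.inner_value) == (832.83, 706.56)


def test_formula_text_regenerates_published_formulas(norms):
    assert formula_text(norms.models["total_accuracy"]) == (
        "Raw + [(-0.106 × (educ - 11.316)) + (0.062 × (age - 61.334))]"
    )
    assert formula_text(norms.models["total_time"]) == "If female: Raw - 68.42"
    assert formula_text(norms.models["reading_time"]) == "No adjustment"
    assert formula_text(norms.models["math_accuracy"]) == "If female: Raw + 0.11"


def test_attention_has_limits_but_no_es_table(norms):
    assert norms.es_tables["attention_accuracy"] is None
    assert norms.limits["attention_accuracy"].outer_value == 1.33
    # every other measure with a correction formula carries an ES table
    for mid, table in norms.es_tables.items():
        if mid != "attention_accuracy":
            assert table is not None and not table.ceiling


def test_es_boundaries_start_at_outer_limit(norms):
    for mid, table in norms.es_tables.items():
        if table is None:
            continue
        assert table.boundaries[0] == norms.limits[mid].outer_value
        assert table.cumulative_ranks == (10, 36, 88, 161, 323)
        assert table.densities == (10, 26, 52, 73, 162)


def test_grid_lookup_serves_printed_cells(norms):
    grid = norms.grids["total_accuracy"]
    assert grid.lookup(75, 5) == 1.413
    assert grid.lookup(52, 16) == -1.109
    assert norms.grids["reading_time"].lookup(75, 5) is None


# --- task aggregation -------------------------------------------------------

def _cards(points_fn, time=10.0):
    return [
        TaskScorecard(tid, points_fn(tid), time)
        for tasks in DEFAULT_TASK_MAP.values()
        for tid in tasks
    ]


def test_all_tasks_at_maximum_reach_subdomain_maxima_and_total_29():
    measures = aggregate_tasks(_cards(lambda t: DEFAULT_TASK_MAXIMA[t]))
    assert measures["total_accuracy"] == pytest.approx(29.0)
    assert measures["attention_accuracy"] == pytest.approx(2.0)
    assert measures["recall_accuracy"] == pytest.approx(5.0)
    assert measures["math_accuracy"] == pytest.approx(1.5)
    assert measures["executive_accuracy"] == pytest.approx(5 / 3)
    assert measures["total_time"] == pytest.approx(19 * 10.0)


def test_all_tasks_at_zero():
    measures = aggregate_tasks(_cards(lambda t: 0.0))
    for mid, value in measures.items():
        if mid.endswith("accuracy"):
            assert value == 0.0


def test_math_tasks_one_and_two_points():
    measures = aggregate_tasks(
        _cards(lambda t: {"math_sum": 1.0, "math_difference": 2.0}.get(t, 0.0))
    )
    assert measures["math_accuracy"] == pytest.approx(1.5)
    assert measures["total_accuracy"] == pytest.approx(3.0)


def test_total_equals_subdomain_means_weighted_by_task_counts():
    import numpy as np

    rng = np.random.default_rng(5)
    cards = _cards(lambda t: float(rng.uniform(0, DEFAULT_TASK_MAXIMA[t])))
    measures = aggregate_tasks(cards)
    weighted = sum(
        measures[f"{sd}_accuracy"] * len(tasks)
        for sd, tasks in DEFAULT_TASK_MAP.items()
    )
    assert measures["total_accuracy"] == pytest.approx(weighted)


def test_missing_task_is_reported_by_id():
    cards = _cards(lambda t: 0.0)[:-1]
    with pytest.raises(ValueError, match="exec_tmt_numbers_letters"):
        aggregate_tasks(cards)


def test_reading_time_is_mean_of_instruction_durations():
    measures = aggregate_tasks(_cards(lambda t: 0.0), reading_times=[10.0, 14.0])
    assert measures["reading_time"] == pytest.approx(12.0)


# --- subject scoring --------------------------------------------------------

def _record(**measures):
    return SubjectRecord("p1", Sex.MALE, 61.334, 11.316, measures)


def test_score_at_cutoff_is_abnormal_es0(norms):
    res = score_subject(_record(total_accuracy=16.5), norms)
    row = res.row("total_accuracy")
    assert row.adjusted == pytest.approx(16.5)
    assert row.classification == "abnormal"
    assert row.es == 0


def test_score_between_limits_is_borderline(norms):
    row = score_subject(_record(total_accuracy=17.5), norms).row("total_accuracy")
    assert row.classification == "borderline"
    assert row.es == 1


def test_score_at_inner_limit_is_normal(norms):
    row = score_subject(_record(total_accuracy=18.57), norms).row("total_accuracy")
    assert row.classification == "normal"


def test_female_total_time_adjustment_and_classification(norms):
    rec = SubjectRecord(
        "p2", Sex.FEMALE, 61.334, 11.316, {"total_time": 900.0}
    )
    row = score_subject(rec, norms).row("total_time")
    assert row.adjusted == pytest.approx(831.579)
    assert row.classification == "borderline"


def test_slow_time_is_abnormal_es0(norms):
    rec = SubjectRecord("p3", Sex.MALE, 61.334, 11.316, {"total_time": 900.0})
    row = score_subject(rec, norms).row("total_time")
    assert row.classification == "abnormal"
    assert row.es == 0


def test_high_accuracy_is_es4(norms):
    row = score_subject(_record(total_accuracy=25.0), norms).row("total_accuracy")
    assert row.es == 4 and row.classification == "normal"


def test_attention_classified_by_limits_only(norms):
    row = score_subject(_record(attention_accuracy=1.0), norms).row(
        "attention_accuracy"
    )
    assert row.es is None
    assert row.classification == "abnormal"


def test_abnormal_iff_es0_across_demographics(norms):
    import numpy as np

    rng = np.random.default_rng(2)
    for _ in range(200):
        rec = SubjectRecord(
            f"r{rng.integers(1e9)}",
            Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
            float(rng.integers(50, 81)),
            float(rng.integers(2, 20)),
            {"total_accuracy": float(rng.uniform(10, 29))},
        )
        row = score_subject(rec, norms).row("total_accuracy")
        assert (row.classification == "abnormal") == (row.es == 0)
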