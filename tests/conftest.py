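import numpy as np
import pytest

from saturn_norms import (
    MeasureSpec,
    NormativeSample,
    Polarity,
    Sex,
    SubjectRecord,
    Units,
    default_saturn_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return default_saturn_catalog()


def make_sample(n=40, seed=0, measure="total_accuracy", values=None, catalog=None):
    """Small hand-rolled sample with both sexes and spread demographics."""
    rng = np.random.default_rng(seed)
    catalog = catalog or default_saturn_catalog()
    if values is None:
        values = rng.uniform(14, 29, size=n)
    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"s{i}",
                sex=Sex.FEMALE if i % 2 else Sex.MALE,
                age=float(rng.integers(50, 81)),
                education=float(rng.integers(2, 20)),
                measures={measure: float(values[i])},
            )
        )
    return NormativeSample(records=tuple(records), catalog=tuple(catalog))


@pytest.fixture
def small_sample():
    return make_sample()
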