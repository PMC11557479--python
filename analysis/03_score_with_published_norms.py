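#!/usr/bin/env python
"""Score example subjects against the published SATURN norms.

Demonstrates the subject-level scorer: demographic adjustment with the
published correction formulas, Equivalent Scores and the
abnormal/borderline/normal classification from the published tolerance
limits.  Writes a per-subject results CSV under results/.
"""

from pathlib import Path

import pandas as pd

from saturn_norms import Sex, SubjectRecord, load_published_norms, score_subject

OUT = Path(__file__).resolve().parents[1] / "results" / "scored_examples.csv"

EXAMPLES = [
    SubjectRecord("low-educ-older", Sex.MALE, 75, 5,
                  {"total_accuracy": 17.0, "total_time": 700.0}),
    SubjectRecord("mean-demographics", Sex.MALE, 61.334, 11.316,
                  {"total_accuracy": 17.5, "total_time": 900.0}),
    SubjectRecord("high-educ-younger", Sex.FEMALE, 52, 18,
                  {"total_accuracy": 27.0, "total_time": 300.0,
                   "math_accuracy": 1.0}),
]


def main() -> None:
    norms = load_published_norms()
    rows = []
    for record in EXAMPLES:
        result = score_subject(record, norms)
        for r in result.rows:
            rows.append({
                "subject_id": record.subject_id,
                "sex": record.sex.value,
                "age": record.age,
                "education": record.education,
                "measure": r.measure_id,
                "raw": r.raw,
                "adjusted": round(r.adjusted, 2),
                "ES": r.es,
                "classification": r.classification,
            })
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT, index=False)
    print(df.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
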