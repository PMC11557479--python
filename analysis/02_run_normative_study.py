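#!/usr/bin/env python
"""Run the full normative study on the simulated cohort.

Reads results/synthetic_cohort.csv (run 01_simulate_cohort.py first),
executes the complete procedure — descriptives, demographic regressions,
adjusted scores, binomial tolerance limits, Equivalent-Score tables and
correction grids — and writes the JSON report plus display tables under
results/normative_report/.
"""

from pathlib import Path

from saturn_norms import StudyConfig, read_sample_csv, run_study, write_report

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "results" / "synthetic_cohort.csv"
OUT = ROOT / "results" / "normative_report"


def main() -> None:
    sample = read_sample_csv(IN)
    report = run_study(sample, StudyConfig())
    paths = write_report(report, OUT)
    print("report files:")
    for p in paths:
        print(f"  {p.relative_to(ROOT)}")

    res = report.measures["total_accuracy"]
    print(f"\ntotal accuracy ranks: outer {res.limits.outer_rank}, "
          f"inner {res.limits.inner_rank}")
    print(f"adjusted outer/inner limits: {res.limits.outer_value:.2f} / "
          f"{res.limits.inner_value:.2f}")
    print(f"ES cumulative ranks: {res.es_table.cumulative_ranks}")
    print(f"correction formula: {report.formula('total_accuracy')}")
    skipped = {m: r.skip_reasons for m, r in report.measures.items() if r.skip_reasons}
    if skipped:
        print(f"skips: {skipped}")


if __name__ == "__main__":
    main()
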