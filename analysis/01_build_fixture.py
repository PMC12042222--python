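"""Build the deterministic fixture cohort and summarise its structure.

Constructs the 14,772-record cohort whose three score bands (<5, 5-7, >=7)
carry exactly the recall/detection counts implied by the published
per-stratum tables, writes a band-level summary to
results/fixture_band_summary.csv and the full cohort CSV to
scratch/fixture_cohort.csv (large, regenerable).
"""

from pathlib import Path

import pandas as pd

from dbt_triage.fixture import BAND_TARGETS, build_fixture_cohort
from dbt_triage.records import write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = build_fixture_cohort()
    df = cohort.frame
    print(f"fixture cohort: {len(cohort)} examinations, {cohort.n_cancers} reference cancers")
    print(f"  detectable by SM double reading : {cohort.detected_count('recall_sm_dr')}")
    print(f"  detectable by DBT double reading: {cohort.detected_count('recall_dbt_dr')}")

    rows = []
    for name, t in BAND_TARGETS.items():
        band = df[df["ai_score"] == {"A": 2.5, "B": 6.0, "C": 8.5}[name]]
        rows.append(
            {
                "band": name,
                "n_exams": len(band),
                "cancers": int(band["cancer"].sum()),
                "sm_dr_recalls": int(band["recall_sm_dr"].sum()),
                "dbt_dr_recalls": int(band["recall_dbt_dr"].sum()),
                "target_n_exams": t.n_exams,
                "target_cancers": t.cancers,
            }
        )
    summary = pd.DataFrame(rows)
    out = ROOT / "results" / "fixture_band_summary.csv"
    out.parent.mkdir(exist_ok=True)
    summary.to_csv(out, index=False)
    print(summary.to_string(index=False))

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    write_cohort(cohort, scratch / "fixture_cohort.csv")
    print(f"full cohort written to {scratch / 'fixture_cohort.csv'}")


if __name__ == "__main__":
    main()
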