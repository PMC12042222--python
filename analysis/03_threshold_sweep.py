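"""Sweep the AI-score threshold from 0 to 10 for all four workflows.

Produces the workload, detection and recall curves as functions of the
threshold (step 0.05) on the fixture cohort, locates the workload-neutral
crossing of the SM-single + DBT-double curve with the 2D double-reading
baseline, and writes results/threshold_sweep.csv.
"""

from pathlib import Path

import numpy as np

from dbt_triage.engine import (
    DR_DBT,
    SR_SM,
    WorkloadModel,
    sweep_thresholds,
    workload_neutral_fraction,
)
from dbt_triage.fixture import build_fixture_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = build_fixture_cohort()
    grid = np.round(np.arange(0.0, 10.0001, 0.05), 10)
    sweep = sweep_thresholds(cohort, WorkloadModel(), grid)
    frame = sweep.as_frame()
    frame.to_csv(ROOT / "results" / "threshold_sweep.csv", index=False)

    baseline = 2.0 * len(cohort)
    w = sweep.curves["sr-sm/dr-dbt"]["workload"].to_numpy()
    crossing = grid[np.argmin(np.abs(w - baseline))]
    p_star = workload_neutral_fraction(SR_SM, DR_DBT, WorkloadModel())
    print(f"grid: {len(grid)} thresholds x {len(sweep.curves)} workflows -> "
          f"{len(frame)} rows written")
    print(f"workload-neutral high-risk fraction p* = {p_star:.4f}")
    print(f"SM-single + DBT-double crosses the 2D double-reading baseline "
          f"({baseline:.0f} units) nearest threshold {crossing:g}")
    print("  (the fixture carries scores at three band atoms, so its workload "
          "curve is a step function and the crossing is coarse; with 30% of "
          "exams at score >= 5, threshold 5 sits just below p* = 1/3 and runs "
          "5% under the baseline)")
    for thr in (5.0, 7.0):
        i = int(np.argmin(np.abs(grid - thr)))
        row = sweep.curves["sr-sm/dr-dbt"].iloc[i]
        print(f"  threshold {thr:g}: workload {row.workload:.0f}, "
              f"recalls {row.recalls:.0f}, detected {row.detected:.0f}")


if __name__ == "__main__":
    main()
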