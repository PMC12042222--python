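import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbt_triage.engine import (
    DR_DBT,
    DR_SM,
    SR_DBT,
    SR_SM,
    WORKFLOWS,
    ReadingArm,
    WorkloadModel,
    WorkflowSpec,
    arm_units,
    dbt_read_percent,
    evaluate_workflow,
    round_half_up,
    summarize_vs_baseline,
    sweep_thresholds,
    workload_neutral_fraction,
)

from .conftest import random_cohort


@pytest.mark.parametrize(
    "arm, ratio, expected",
    [
        (SR_SM, 2.0, 1.0),
        (DR_SM, 2.0, 2.0),
        (SR_DBT, 2.0, 2.0),
        (DR_DBT, 2.0, 4.0),
        (SR_SM, 1.7, 1.0),
        (SR_DBT, 1.7, 1.7),
        (DR_DBT, 1.7, 3.4),
    ],
)
def test_arm_units(arm, ratio, expected):
    assert arm_units(arm, WorkloadModel(ratio_r=ratio)) == pytest.approx(expected)


def _oracle_evaluate(cohort, spec, model):
    """Independent per-record accumulation (different grouping order)."""
    acc = {
        "sm": dict(read=0, recalls=0, fp=0, det=0, cancers=0),
        "dbt": dict(read=0, recalls=0, fp=0, det=0, cancers=0),
    }
    for rec in cohort.frame.itertuples(index=False):
        key = "dbt" if rec.ai_score >= spec.threshold else "sm"
        arm = spec.high_risk_arm if key == "dbt" else spec.low_risk_arm
        recall = getattr(rec, arm.recall_column)
        a = acc[key]
        a["read"] += 1
        a["cancers"] += rec.cancer
        if recall:
            a["recalls"] += 1
            if rec.cancer:
                a["det"] += 1
            else:
                a["fp"] += 1
    out = {}
    for key, arm in (("sm", spec.low_risk_arm), ("dbt", spec.high_risk_arm)):
        a = acc[key]
        out[key] = dict(
            read_exams=a["read"],
            workload=a["read"] * arm_units(arm, model),
            recalls=a["recalls"],
            fp_recalls=a["fp"],
            detected=a["det"],
            non_detected=a["cancers"] - a["det"],
        )
    return out


@pytest.mark.parametrize("seed", range(100))
def test_oracle_equivalence_on_random_cohorts(seed):
    """Vectorised evaluation agrees with a per-record loop on 100 random cohorts."""
    cohort = random_cohort(seed)
    rng = np.random.default_rng(seed + 10_000)
    threshold = float(rng.uniform(0, 10))
    low, high = WORKFLOWS[list(WORKFLOWS)[seed % 4]]
    model = WorkloadModel(ratio_r=float(rng.uniform(1.0, 3.0)))
    spec = WorkflowSpec(low, high, threshold)
    result = evaluate_workflow(cohort, spec, model)
    expected = _oracle_evaluate(cohort, spec, model)
    assert result.sm_stratum.as_dict() == pytest.approx(expected["sm"])
    assert result.dbt_stratum.as_dict() == pytest.approx(expected["dbt"])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000), threshold=st.floats(0, 10), wf=st.sampled_from(sorted(WORKFLOWS)))
def test_conservation_and_additivity(seed, threshold, wf):
    """recalls = FP + detected per stratum; totals are componentwise sums;
    detected + non-detected = reference cancers."""
    cohort = random_cohort(seed % 97, n=300)
    low, high = WORKFLOWS[wf]
    result = evaluate_workflow(cohort, WorkflowSpec(low, high, threshold))
    for s in (result.sm_stratum, result.dbt_stratum, result.total):
        assert s.recalls == s.fp_recalls + s.detected
    assert result.total == result.sm_stratum + result.dbt_stratum
    assert result.total.detected + result.total.non_detected == cohort.n_cancers


def test_boundary_equivalence():
    """Threshold 0 applies the high-risk arm to everyone; a threshold above
    the maximum score applies the low-risk arm to everyone."""
    cohort = random_cohort(3, n=500)
    spec0 = WorkflowSpec(SR_SM, DR_DBT, 0.0)
    res0 = evaluate_workflow(cohort, spec0)
    assert res0.sm_stratum.read_exams == 0
    assert res0.total.recalls == int(cohort.frame["recall_dbt_dr"].sum())
    assert res0.total.workload == 4.0 * len(cohort)

    hi = float(np.nextafter(cohort.frame["ai_score"].max(), 11.0))
    hi = min(hi, 10.0)
    res_hi = evaluate_workflow(cohort, WorkflowSpec(SR_SM, DR_DBT, hi))
    if (cohort.frame["ai_score"] >= hi).sum() == 0:
        assert res_hi.dbt_stratum.read_exams == 0
        assert res_hi.total.recalls == int(cohort.frame["recall_sm_sr"].sum())


def test_threshold_out_of_range_rejected():
    with pytest.raises(ValueError, match=r"\[0.0, 10.0\]"):
        WorkflowSpec(SR_SM, DR_DBT, 12.0)


def test_sweep_matches_pointwise_evaluation(fixture_cohort):
    grid = [0.0, 2.5, 5.0, 6.0, 7.0, 9.99, 10.0]
    sweep = sweep_thresholds(fixture_cohort, WorkloadModel(), grid)
    for key, (low, high) in WORKFLOWS.items():
        curve = sweep.curves[key]
        for i, thr in enumerate(grid):
            res = evaluate_workflow(fixture_cohort, WorkflowSpec(low, high, thr))
            assert curve.loc[i, "workload"] == res.total.workload
            assert curve.loc[i, "recalls"] == res.total.recalls
            assert curve.loc[i, "detected"] == res.total.detected


def test_sweep_workload_monotone_when_high_arm_costlier(fixture_cohort):
    """Workload never increases with the threshold when the high-risk arm
    costs at least as much per exam as the low-risk arm."""
    grid = np.round(np.arange(0, 10.0001, 0.05), 10)
    sweep = sweep_thresholds(fixture_cohort, WorkloadModel(), grid)
    for key in ("sr-sm/dr-dbt", "sr-sm/sr-dbt", "dr-sm/dr-dbt"):
        w = sweep.curves[key]["workload"].to_numpy()
        assert np.all(np.diff(w) <= 0)
    flat = sweep.curves["dr-sm/sr-dbt"]["workload"].to_numpy()
    assert np.all(flat == flat[0])  # equal per-exam units: threshold-independent


def test_sweep_rejects_unsorted_grid(fixture_cohort):
    with pytest.raises(ValueError, match="sorted"):
        sweep_thresholds(fixture_cohort, grid=[5.0, 3.0])


@pytest.mark.parametrize(
    "low, high, ratio, expected",
    [
        (SR_SM, DR_DBT, 2.0, 1 / 3),
        (DR_SM, SR_DBT, 2.0, None),
        (SR_SM, DR_DBT, 1.7, 1 / 2.4),
    ],
)
def test_workload_neutral_fraction_closed_form(low, high, ratio, expected):
    got = workload_neutral_fraction(low, high, WorkloadModel(ratio_r=ratio))
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


def test_workload_neutral_threshold_is_score_quantile():
    """On a uniform-score cohort, the workload curve crosses the 2-units/exam
    baseline at the score quantile of p* = 1/3."""
    cohort = random_cohort(123, n=900)
    grid = np.round(np.arange(0, 10.0001, 0.05), 10)
    sweep = sweep_thresholds(cohort, WorkloadModel(), grid)
    w = sweep.curves["sr-sm/dr-dbt"]["workload"].to_numpy()
    baseline = 2.0 * len(cohort)
    cross = grid[np.argmin(np.abs(w - baseline))]
    p_star = workload_neutral_fraction(SR_SM, DR_DBT, WorkloadModel())
    expected = np.quantile(cohort.frame["ai_score"], 1 - p_star)
    assert abs(cross - expected) <= 0.1  # within grid resolution


def test_round_half_up():
    assert round_half_up(13.835) == 14
    assert round_half_up(0.5) == 1
    assert round_half_up(8.4617, 2) == 8.46
    assert round_half_up(-2.5) == -3


def test_summary_vs_baseline_rounding(fixture_cohort):
    result = evaluate_workflow(fixture_cohort, WorkflowSpec(SR_SM, DR_DBT, 5.0))
    summary = summarize_vs_baseline(
        result,
        baseline_detected=95,
        baseline_workload=2.0 * 14_772,
        dbt_dr_detected=127,
        n_exams=14_772,
    )
    assert summary["pct_more_than_baseline"] == 28
    assert summary["pct_of_dbt_dr_detectable"] == 96
    assert summary["pct_workload_change"] == -5
    assert summary["detection_rate_per_1000"] == 8.26


def test_summary_rejects_zero_baselines(fixture_cohort):
    result = evaluate_workflow(fixture_cohort, WorkflowSpec(SR_SM, DR_DBT, 5.0))
    with pytest.raises(ValueError, match="positive"):
        summarize_vs_baseline(result, 0, 1000.0, 127, 14_772)


def test_dbt_read_percent(fixture_cohort):
    assert dbt_read_percent(fixture_cohort, 5.0) == 30
    assert dbt_read_percent(fixture_cohort, 7.0) == 22
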