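import pytest

from dbt_triage.capacity import ClinicParams, annual_reading_seconds, estimate_fte
from dbt_triage.engine import DR_DBT, DR_SM, SR_SM, WorkflowSpec, evaluate_workflow


@pytest.fixture(scope="module")
def clinic():
    return ClinicParams()


@pytest.fixture(scope="module")
def threshold5_result(fixture_cohort):
    spec = WorkflowSpec(SR_SM, DR_DBT, 5.0)
    return evaluate_workflow(fixture_cohort, spec), spec


def test_uniform_double_reading_seconds(fixture_cohort, clinic):
    """All 68,000 exams double-read at 40 s: 5,440,000 s a year."""
    spec = WorkflowSpec(DR_SM, DR_DBT, 10.0)  # above every fixture score: all SM
    result = evaluate_workflow(fixture_cohort, spec)
    assert result.dbt_stratum.read_exams == 0
    assert annual_reading_seconds(result, spec, clinic, len(fixture_cohort)) == pytest.approx(
        68_000 * 2 * 40
    )


def test_triage_reading_seconds_match_hand_computation(threshold5_result, clinic):
    result, spec = threshold5_result
    expected = 68_000 * (10_320 / 14_772 * 1 * 40 + 4_452 / 14_772 * 2 * 80)
    assert annual_reading_seconds(result, spec, clinic, 14_772) == pytest.approx(expected)


def test_fte_components_and_total(threshold5_result, clinic):
    result, spec = threshold5_result
    report = estimate_fte(result, spec, clinic, 14_772, dbt_dr_detected=127)
    seconds = annual_reading_seconds(result, spec, clinic, 14_772)
    assert report.fte_screen_reading == pytest.approx(seconds / (40 * 45 * 3600))
    annual_recalls = 68_000 * result.total.recalls / 14_772
    assert report.fte_recall_workup == pytest.approx(annual_recalls / (20 * 225))
    assert report.fte_referrals == pytest.approx(10_500 / 4_500)
    assert report.fte_total == pytest.approx(
        report.fte_screen_reading + report.fte_recall_workup + report.fte_referrals
    )
    assert report.relative_detection == pytest.approx(122 / 127)


def test_referral_fte_independent_of_workflow(fixture_cohort, clinic):
    reports = []
    for spec in (WorkflowSpec(SR_SM, DR_DBT, 5.0), WorkflowSpec(DR_SM, DR_DBT, 7.0)):
        result = evaluate_workflow(fixture_cohort, spec)
        reports.append(estimate_fte(result, spec, clinic, len(fixture_cohort), 127))
    assert reports[0].fte_referrals == reports[1].fte_referrals


def test_scaling_linearity(threshold5_result, clinic):
    result, spec = threshold5_result
    double = clinic.model_copy(update={"annual_screens": 2 * clinic.annual_screens})
    base = estimate_fte(result, spec, clinic, 14_772, 127)
    big = estimate_fte(result, spec, double, 14_772, 127)
    assert big.fte_screen_reading == pytest.approx(2 * base.fte_screen_reading)
    assert big.fte_recall_workup == pytest.approx(2 * base.fte_recall_workup)
    assert big.fte_referrals == pytest.approx(base.fte_referrals)


def test_screen_reading_ordering_on_fixture(fixture_cohort, clinic):
    """Per-exam reading seconds at threshold 5 order the workflows; the
    test asserts the ordering the arithmetic yields, computed fresh."""
    specs = {
        "sr-sm/dr-dbt": WorkflowSpec(SR_SM, DR_DBT, 5.0),
        "dr-sm/dr-dbt": WorkflowSpec(DR_SM, DR_DBT, 5.0),
        "uniform-dbt-dr": WorkflowSpec(DR_SM, DR_DBT, 0.0),
        "uniform-sm-dr": WorkflowSpec(DR_SM, DR_DBT, 10.0),
    }
    seconds = {}
    for name, spec in specs.items():
        result = evaluate_workflow(fixture_cohort, spec)
        seconds[name] = annual_reading_seconds(result, spec, clinic, len(fixture_cohort))
    # triaged SM-single/DBT-double averages ~76.2 s/exam, just below the
    # 80 s/exam of uniform 2D double reading
    assert seconds["sr-sm/dr-dbt"] < seconds["uniform-sm-dr"]
    assert seconds["uniform-sm-dr"] < seconds["dr-sm/dr-dbt"]
    assert seconds["dr-sm/dr-dbt"] < seconds["uniform-dbt-dr"]


def test_zero_recall_workflow_needs_no_workup_fte(clinic):
    from dbt_triage.records import CohortTable

    from .conftest import random_cohort

    df = random_cohort(9, n=50).frame.copy()
    for col in ("recall_sm_sr", "recall_sm_dr", "recall_dbt_sr", "recall_dbt_dr"):
        df[col] = False
    quiet = CohortTable(df)
    spec = WorkflowSpec(SR_SM, DR_DBT, 5.0)
    result = evaluate_workflow(quiet, spec)
    report = estimate_fte(result, spec, clinic, len(quiet), dbt_dr_detected=1)
    assert report.fte_recall_workup == 0.0


def test_invalid_clinic_params_rejected():
    with pytest.raises(ValueError):
        ClinicParams(annual_screens=0)
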