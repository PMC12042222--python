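"""Clinic-level workforce model.

Converts a triage workflow's reading volumes and recall rate into
full-time-equivalent (FTE) radiologist requirements for a breast
radiology clinic handling three tasks: screen reading, workup of women
recalled from screening, and clinical referrals from other clinics.

The defaults describe an example clinic: 68,000 screening examinations a
year, a reading time of 40 s per SM/DM read and 80 s per DBT read, a
workup capacity of 20 recalled or clinically referred women per full
radiologist-day, 10,500 symptomatic referrals a year (assumed unaffected
by the screening workflow), and 40-hour work weeks.  The working calendar
(45 working weeks and 225 working days a year) is configurable; annual
hours and days are not pinned by the example and matter only as a common
scale factor across workflows.
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field

from .engine import Modality, WorkflowResult, WorkflowSpec


class ClinicParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    annual_screens: int = Field(default=68_000, gt=0)
    read_seconds_sm: float = Field(default=40.0, gt=0)
    read_seconds_dbt: float = Field(default=80.0, gt=0)
    workup_capacity: float = Field(default=20.0, gt=0, description="women per radiologist-day")
    annual_referrals: int = Field(default=10_500, gt=0)
    weekly_hours: float = Field(default=40.0, gt=0)
    working_days_per_year: float = Field(default=225.0, gt=0)
    working_weeks_per_year: float = Field(default=45.0, gt=0)

    @property
    def annual_seconds_per_fte(self) -> float:
        return self.weekly_hours * self.working_weeks_per_year * 3600.0

    @property
    def annual_workups_per_fte(self) -> float:
        return self.workup_capacity * self.working_days_per_year


@dataclass(frozen=True)
class ClinicReport:
    fte_screen_reading: float
    fte_recall_workup: float
    fte_referrals: float
    fte_total: float
    relative_detection: float

    def __post_init__(self) -> None:
        if min(self.fte_screen_reading, self.fte_recall_workup, self.fte_referrals) < 0:
            raise ValueError("FTE components must be non-negative")
        if not (0.0 <= self.relative_detection <= 1.0):
            raise ValueError("relative_detection must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "fte_screen_reading": self.fte_screen_reading,
            "fte_recall_workup": self.fte_recall_workup,
            "fte_referrals": self.fte_referrals,
            "fte_total": self.fte_total,
            "relative_detection": self.relative_detection,
        }


def _seconds_per_read(modality: Modality, clinic: ClinicParams) -> float:
    return clinic.read_seconds_sm if modality is Modality.SM else clinic.read_seconds_dbt


def annual_reading_seconds(
    result: WorkflowResult,
    spec: WorkflowSpec,
    clinic: ClinicParams,
    cohort_size: int,
) -> float:
    """Annual screen-reading seconds for a workflow, scaled to clinic volume.

    The cohort's stratum proportions are scaled to ``annual_screens``;
    each stratum contributes (share x readers x seconds-per-read).
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    share_sm = result.sm_stratum.read_exams / cohort_size
    share_dbt = result.dbt_stratum.read_exams / cohort_size
    per_exam = share_sm * spec.low_risk_arm.n_readers * _seconds_per_read(
        spec.low_risk_arm.modality, clinic
    ) + share_dbt * spec.high_risk_arm.n_readers * _seconds_per_read(
        spec.high_risk_arm.modality, clinic
    )
    return clinic.annual_screens * per_exam


def estimate_fte(
    result: WorkflowResult,
    spec: WorkflowSpec,
    clinic: ClinicParams,
    cohort_size: int,
    dbt_dr_detected: int,
) -> ClinicReport:
    """Full FTE breakdown for one workflow.

    ``relative_detection`` is the workflow's detected cancers as a
    fraction of the cancers detectable by uniform DBT double reading
    (``dbt_dr_detected``), the pie-chart quantity of the clinic example.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if dbt_dr_detected <= 0:
        raise ValueError("dbt_dr_detected must be positive")
    fte_reading = annual_reading_seconds(result, spec, clinic, cohort_size) / clinic.annual_seconds_per_fte
    annual_recalls = clinic.annual_screens * result.total.recalls / cohort_size
    fte_workup = annual_recalls / clinic.annual_workups_per_fte
    fte_referrals = clinic.annual_referrals / clinic.annual_workups_per_fte
    return ClinicReport(
        fte_screen_reading=fte_reading,
        fte_recall_workup=fte_workup,
        fte_referrals=fte_referrals,
        fte_total=fte_reading + fte_workup + fte_referrals,
        relative_detection=result.total.detected / dbt_dr_detected,
    )
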