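"""Threshold-triage evaluation of SM/DBT reading workflows.

A triage workflow sends every examination with AI score at or above a
threshold to a DBT reading arm (the high-risk stratum) and the rest to an
SM reading arm (the low-risk stratum).  Each arm is single or double
reading, so four workflow combinations exist.  Workload is counted in
reading-time equivalents: one single SM read = 1 unit, one DBT read = r
units (default r = 2), and double reading doubles the per-exam units.

For each stratum the engine reports read examinations, workload, recalls,
false-positive recalls, detected cancers, and non-detected cancers, where
"non-detected" counts reference cancers whose AI score places them in the
stratum but which the stratum's arm does not recall.  The reference cancer
set is the set of cancers detectable by combined SM and DBT double reading
(135 in the default study structure).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import SCORE_MAX, SCORE_MIN, CohortTable


class Modality(str, enum.Enum):
    SM = "sm"
    DBT = "dbt"


class Readers(str, enum.Enum):
    SINGLE = "sr"
    DOUBLE = "dr"


@dataclass(frozen=True)
class ReadingArm:
    """One of the four reading arms (SM/DBT x single/double)."""

    modality: Modality
    readers: Readers

    @property
    def recall_column(self) -> str:
        return f"recall_{self.modality.value}_{self.readers.value}"

    @property
    def n_readers(self) -> int:
        return 1 if self.readers is Readers.SINGLE else 2

    def __str__(self) -> str:
        return f"{self.readers.value}-{self.modality.value}"

    @classmethod
    def parse(cls, label: str) -> "ReadingArm":
        """Parse labels like ``"sr-sm"``, ``"dr-dbt"``, ``"SR DBT"``."""
        token = label.strip().lower().replace(" ", "-").replace("_", "-")
        try:
            readers, modality = token.split("-")
            return cls(Modality(modality), Readers(readers))
        except ValueError as exc:
            raise ValueError(
                f"unknown reading arm {label!r}; expected one of "
                "sr-sm, dr-sm, sr-dbt, dr-dbt"
            ) from exc


SR_SM = ReadingArm(Modality.SM, Readers.SINGLE)
DR_SM = ReadingArm(Modality.SM, Readers.DOUBLE)
SR_DBT = ReadingArm(Modality.DBT, Readers.SINGLE)
DR_DBT = ReadingArm(Modality.DBT, Readers.DOUBLE)

#: The four triage workflow combinations, keyed as "<low>/<high>".
WORKFLOWS: Mapping[str, tuple[ReadingArm, ReadingArm]] = {
    "sr-sm/sr-dbt": (SR_SM, SR_DBT),
    "sr-sm/dr-dbt": (SR_SM, DR_DBT),
    "dr-sm/sr-dbt": (DR_SM, SR_DBT),
    "dr-sm/dr-dbt": (DR_SM, DR_DBT),
}


@dataclass(frozen=True)
class WorkloadModel:
    """Reading-time-equivalent accounting.

    ``ratio_r`` is the reading time of one DBT read in units of one SM
    read; the default 2.0 reflects reported DBT reading times roughly
    twice those of 2D mammography, with 1.7 as a less conservative
    alternative.
    """

    ratio_r: float = 2.0

    def __post_init__(self) -> None:
        if not self.ratio_r > 0:
            raise ValueError(f"ratio_r must be positive, got {self.ratio_r}")


def arm_units(arm: ReadingArm, model: WorkloadModel) -> float:
    """Reading-time equivalents for one examination read under ``arm``."""
    per_read = 1.0 if arm.modality is Modality.SM else model.ratio_r
    return arm.n_readers * per_read


@dataclass(frozen=True)
class WorkflowSpec:
    """A triage rule: SM arm below the threshold, DBT arm at or above it."""

    low_risk_arm: ReadingArm
    high_risk_arm: ReadingArm
    threshold: float

    def __post_init__(self) -> None:
        if self.low_risk_arm.modality is not Modality.SM:
            raise ValueError("low_risk_arm must read SM")
        if self.high_risk_arm.modality is not Modality.DBT:
            raise ValueError("high_risk_arm must read DBT")
        if not (SCORE_MIN <= self.threshold <= SCORE_MAX):
            raise ValueError(
                f"threshold must be in [{SCORE_MIN}, {SCORE_MAX}], got {self.threshold}"
            )


@dataclass(frozen=True)
class StratumSummary:
    """One row of the per-stratum results table."""

    read_exams: int
    workload: float
    recalls: int
    fp_recalls: int
    detected: int
    non_detected: int

    def __post_init__(self) -> None:
        counts = (self.read_exams, self.recalls, self.fp_recalls, self.detected, self.non_detected)
        if any(c < 0 for c in counts) or self.workload < 0:
            raise ValueError(f"negative count in stratum summary: {self}")
        if self.recalls != self.fp_recalls + self.detected:
            raise ValueError(
                f"recalls ({self.recalls}) != false positives ({self.fp_recalls})"
                f" + detected ({self.detected})"
            )

    def __add__(self, other: "StratumSummary") -> "StratumSummary":
        return StratumSummary(
            read_exams=self.read_exams + other.read_exams,
            workload=self.workload + other.workload,
            recalls=self.recalls + other.recalls,
            fp_recalls=self.fp_recalls + other.fp_recalls,
            detected=self.detected + other.detected,
            non_detected=self.non_detected + other.non_detected,
        )

    def as_dict(self) -> dict:
        return {
            "read_exams": self.read_exams,
            "workload": self.workload,
            "recalls": self.recalls,
            "fp_recalls": self.fp_recalls,
            "detected": self.detected,
            "non_detected": self.non_detected,
        }


@dataclass(frozen=True)
class WorkflowResult:
    sm_stratum: StratumSummary
    dbt_stratum: StratumSummary
    total: StratumSummary
    reference_cancers: int

    def __post_init__(self) -> None:
        if self.total != self.sm_stratum + self.dbt_stratum:
            raise ValueError("total stratum is not the componentwise sum of SM and DBT strata")
        if self.total.detected + self.total.non_detected != self.reference_cancers:
            raise ValueError(
                f"detected ({self.total.detected}) + non-detected "
                f"({self.total.non_detected}) != reference cancers "
                f"({self.reference_cancers})"
            )

    def as_dict(self) -> dict:
        return {
            "sm": self.sm_stratum.as_dict(),
            "dbt": self.dbt_stratum.as_dict(),
            "total": self.total.as_dict(),
            "reference_cancers": self.reference_cancers,
        }


def _stratum_summary(
    df: pd.DataFrame, arm: ReadingArm, model: WorkloadModel
) -> StratumSummary:
    recall = df[arm.recall_column]
    cancer = df["cancer"]
    recalls = int(recall.sum())
    detected = int((recall & cancer).sum())
    return StratumSummary(
        read_exams=len(df),
        workload=len(df) * arm_units(arm, model),
        recalls=recalls,
        fp_recalls=recalls - detected,
        detected=detected,
        non_detected=int(cancer.sum()) - detected,
    )


def evaluate_workflow(
    cohort: CohortTable,
    spec: WorkflowSpec,
    model: WorkloadModel = WorkloadModel(),
    reference_cancers: int | None = None,
) -> WorkflowResult:
    """Evaluate one workflow at one threshold on a cohort.

    Examinations with ``ai_score >= spec.threshold`` form the DBT (high
    risk) stratum; the rest form the SM stratum.  ``reference_cancers``
    defaults to the number of cancers in the cohort; it is the denominator
    against which non-detected counts are accounted.
    """
    df = cohort.frame
    if reference_cancers is None:
        reference_cancers = cohort.n_cancers
    high = df["ai_score"] >= spec.threshold
    sm = _stratum_summary(df.loc[~high], spec.low_risk_arm, model)
    dbt = _stratum_summary(df.loc[high], spec.high_risk_arm, model)
    total = sm + dbt
    if reference_cancers < total.detected:
        raise ValueError(
            f"reference_cancers ({reference_cancers}) is smaller than the "
            f"number of detected cancers ({total.detected})"
        )
    # Cancers outside the reference set would make per-stratum accounting
    # inconsistent; the cohort defines the reference set, so they must agree.
    if cohort.n_cancers != reference_cancers:
        raise ValueError(
            f"cohort has {cohort.n_cancers} cancers but reference_cancers is "
            f"{reference_cancers}; the cohort cancer set is the reference set"
        )
    return WorkflowResult(sm, dbt, total, reference_cancers)


@dataclass(frozen=True)
class SweepResult:
    """Workload/detection/recall curves over a threshold grid, per workflow."""

    thresholds: np.ndarray
    curves: Mapping[str, pd.DataFrame]  # workflow key -> columns workload/recalls/detected

    def as_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (threshold, workflow)."""
        parts = []
        for key, df in self.curves.items():
            part = df.copy()
            part.insert(0, "workflow", key)
            part.insert(0, "threshold", self.thresholds)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def sweep_thresholds(
    cohort: CohortTable,
    model: WorkloadModel = WorkloadModel(),
    grid: Sequence[float] | np.ndarray | None = None,
) -> SweepResult:
    """Evaluate all four workflow combinations over a threshold grid.

    The default grid is 0 to 10 in steps of 0.05, mirroring a continuous
    threshold variation.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 10.0 + 1e-9, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted in non-decreasing order")
    if grid[0] < SCORE_MIN or grid[-1] > SCORE_MAX:
        raise ValueError("grid values must lie in [0, 10]")

    df = cohort.frame
    order = np.argsort(df["ai_score"].to_numpy(), kind="stable")
    scores = df["ai_score"].to_numpy()[order]
    cancer = df["cancer"].to_numpy()[order]
    n = len(df)

    curves: dict[str, pd.DataFrame] = {}
    for key, (low, high) in WORKFLOWS.items():
        low_units = arm_units(low, model)
        high_units = arm_units(high, model)
        rec_low = df[low.recall_column].to_numpy()[order]
        rec_high = df[high.recall_column].to_numpy()[order]
        # cum_low[k] = count among the k lowest-score exams (the SM stratum
        # when k exams fall below the threshold).
        cum_low = np.concatenate(([0], np.cumsum(rec_low)))
        cum_low_det = np.concatenate(([0], np.cumsum(rec_low & cancer)))
        cum_high = np.concatenate(([0], np.cumsum(rec_high[::-1])))[::-1]
        cum_high_det = np.concatenate(([0], np.cumsum((rec_high & cancer)[::-1])))[::-1]
        # number of exams strictly below each threshold
        k = np.searchsorted(scores, grid, side="left")
        workload = k * low_units + (n - k) * high_units
        recalls = cum_low[k] + cum_high[k]
        detected = cum_low_det[k] + cum_high_det[k]
        curves[key] = pd.DataFrame(
            {
                "workload": workload.astype(float),
                "recalls": recalls.astype(int),
                "detected": detected.astype(int),
            }
        )
    return SweepResult(thresholds=grid, curves=curves)


def workload_neutral_fraction(
    low: ReadingArm,
    high: ReadingArm,
    model: WorkloadModel = WorkloadModel(),
    baseline_units_per_exam: float = 2.0,
) -> float | None:
    """High-risk fraction at which a workflow's workload equals a baseline.

    Solves ``a (1 - p) + b p = baseline`` for p, where a and b are the
    per-exam units of the low- and high-risk arms.  Returns ``None`` when
    the arms have equal units (workload is threshold-independent) or when
    the solution falls outside [0, 1].

    The default baseline of 2 units/exam is uniform double-read SM, i.e.
    conventional 2D double reading.
    """
    if not baseline_units_per_exam > 0:
        raise ValueError("baseline_units_per_exam must be positive")
    a = arm_units(low, model)
    b = arm_units(high, model)
    if math.isclose(a, b):
        return None
    p = (baseline_units_per_exam - a) / (b - a)
    if not (0.0 <= p <= 1.0):
        return None
    return p


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention used for reported percentages)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def summarize_vs_baseline(
    result: WorkflowResult,
    baseline_detected: int,
    baseline_workload: float,
    dbt_dr_detected: int,
    n_exams: int,
) -> dict:
    """Derived comparison quantities for one workflow evaluation.

    Returns percent change in detection versus a baseline arm (e.g. the 95
    cancers of uniform double-read 2D mammography), the percent of
    DBT-double-reading-detectable cancers found, percent workload change
    versus a baseline workload, and the detection rate per 1000 screened.
    Percentages are rounded half-up to integers; rates per 1000 to two
    decimals.
    """
    if baseline_detected <= 0 or baseline_workload <= 0 or dbt_dr_detected <= 0 or n_exams <= 0:
        raise ValueError("baselines and n_exams must be positive")
    detected = result.total.detected
    return {
        "detected": detected,
        "pct_more_than_baseline": int(
            round_half_up(100.0 * (detected - baseline_detected) / baseline_detected)
        ),
        "pct_of_dbt_dr_detectable": int(round_half_up(100.0 * detected / dbt_dr_detected)),
        "pct_workload_change": int(
            round_half_up(100.0 * (result.total.workload - baseline_workload) / baseline_workload)
        ),
        "detection_rate_per_1000": round_half_up(1000.0 * detected / n_exams, 2),
    }


def dbt_read_percent(cohort: CohortTable, threshold: float) -> int:
    """Percent of examinations triaged to the DBT stratum, rounded half-up."""
    df = cohort.frame
    frac = float((df["ai_score"] >= threshold).mean())
    return int(round_half_up(100.0 * frac))
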