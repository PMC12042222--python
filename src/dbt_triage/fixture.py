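"""Deterministic fixture cohort reproducing the published stratum tables.

The study population (14,772 screened women) is not deposited, but every
cell of the two published results tables — per-stratum read examinations,
recalls, false-positive recalls, detected and non-detected cancers for all
four workflows at thresholds 5 and 7 — is printed, together with the
global cancer totals (135 cancers detectable by combined double reading,
95 by SM/DM double reading, 127 by DBT double reading).

Because the two tables stratify the same cohort at two thresholds, their
difference pins down per-band counts over three AI-score bands:

* band A: score < 5        (10,320 exams)
* band B: 5 <= score < 7   ( 1,185 exams)
* band C: score >= 7       ( 3,267 exams)

This module assigns recall flags record-by-record inside each band so that
every band-level count is hit exactly.  A few counts are not determined by
the tables (e.g. SM recalls inside band C, which is never SM-read at
thresholds 5 or 7); those are fixed at documented representative values so
that the cohort is fully specified and threshold sweeps are well defined.
Representative AI scores are fixed band midpoints (2.5, 6.0, 8.5); any
scores inside the half-open band intervals give identical results at
thresholds 5 and 7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import CohortTable

#: Fixed representative score for each band.
BAND_SCORES = {"A": 2.5, "B": 6.0, "C": 8.5}


@dataclass(frozen=True)
class BandTargets:
    """Exact per-band counts the fixture must reproduce.

    ``*_recalls`` are total recalls (cancer + false positive) under the
    arm; ``*_detected`` are recalls among cancers.  ``cancers_sm_dr`` /
    ``cancers_dbt_dr`` are the cancers in the band detectable by the
    respective double-reading arm; their union must cover all ``cancers``
    in the band (the reference set is defined by combined double reading).
    """

    n_exams: int
    cancers: int
    cancers_sm_dr: int
    cancers_dbt_dr: int
    sm_sr_detected: int
    sm_dr_detected: int
    dbt_sr_detected: int
    dbt_dr_detected: int
    sm_sr_fp: int
    sm_dr_fp: int
    dbt_sr_fp: int
    dbt_dr_fp: int


# Band-level targets.  Table-determined entries are differences of the two
# printed tables; entries marked "free" are not determined by any printed
# cell and are fixed here once (see module docstring).
BAND_TARGETS: dict[str, BandTargets] = {
    # Band A = SM stratum at threshold 5: SM-SR 107 recalls / 101 FP / 6
    # detected; SM-DR 145 / 136 / 9.  13 cancers (6+7).  DBT counts free
    # except cancers_dbt_dr = 127 - 116 (DBT-DR detectable below score 5).
    "A": BandTargets(
        n_exams=10_320,
        cancers=13,
        cancers_sm_dr=9,
        cancers_dbt_dr=11,
        sm_sr_detected=6,
        sm_dr_detected=9,
        dbt_sr_detected=9,  # free: <= cancers_dbt_dr
        dbt_dr_detected=11,
        sm_sr_fp=101,
        sm_dr_fp=136,
        dbt_sr_fp=120,  # free: band never DBT-read at thresholds 5/7
        dbt_dr_fp=160,  # free
    ),
    # Band B = threshold-7 SM stratum minus threshold-5 SM stratum, and
    # threshold-5 DBT stratum minus threshold-7 DBT stratum.
    "B": BandTargets(
        n_exams=1_185,
        cancers=4,  # 17 - 13
        cancers_sm_dr=3,  # 12 - 9
        cancers_dbt_dr=4,  # 116 - 112
        sm_sr_detected=2,  # 8 - 6
        sm_dr_detected=3,  # 12 - 9
        dbt_sr_detected=4,  # 105 - 101
        dbt_dr_detected=4,  # 116 - 112
        sm_sr_fp=22,  # 123 - 101
        sm_dr_fp=29,  # 165 - 136
        dbt_sr_fp=25,  # 176 - 151
        dbt_dr_fp=35,  # 211 - 176
    ),
    # Band C = DBT stratum at threshold 7: DBT-SR 252 / 151 / 101; DBT-DR
    # 288 / 176 / 112.  118 cancers (112 + 6).  SM counts free except
    # cancers_sm_dr = 95 - 12 (SM-DR detectable at score >= 7).
    "C": BandTargets(
        n_exams=3_267,
        cancers=118,
        cancers_sm_dr=83,
        cancers_dbt_dr=112,
        sm_sr_detected=55,  # free: <= cancers_sm_dr
        sm_dr_detected=83,
        dbt_sr_detected=101,
        dbt_dr_detected=112,
        sm_sr_fp=70,  # free: band never SM-read at thresholds 5/7
        sm_dr_fp=95,  # free
        dbt_sr_fp=151,
        dbt_dr_fp=176,
    ),
}

#: Global cancer totals the bands must add up to.
REFERENCE_CANCERS = 135
SM_DR_DETECTABLE = 95
DBT_DR_DETECTABLE = 127
N_EXAMS = 14_772


class FixtureConsistencyError(RuntimeError):
    """Raised when the band targets have been edited into infeasibility."""


def _check_band(name: str, t: BandTargets) -> None:
    def fail(msg: str) -> None:
        raise FixtureConsistencyError(f"band {name}: {msg}")

    if t.cancers > t.n_exams:
        fail("more cancers than examinations")
    # combined double reading must cover every reference cancer in the band
    overlap = t.cancers_sm_dr + t.cancers_dbt_dr - t.cancers
    if overlap < 0:
        fail("SM-DR and DBT-DR detectable sets cannot cover all cancers")
    if overlap > min(t.cancers_sm_dr, t.cancers_dbt_dr):
        fail("detectable-set overlap exceeds the smaller set")
    # detected = recalled under the arm; DR detected equals the detectable
    # count (double reading defines detectability), SR nested inside DR
    if t.sm_dr_detected != t.cancers_sm_dr or t.dbt_dr_detected != t.cancers_dbt_dr:
        fail("double-reading detected counts must equal the detectable-set sizes")
    if not (0 <= t.sm_sr_detected <= t.sm_dr_detected):
        fail("SM single-reading detected not nested in double-reading detected")
    if not (0 <= t.dbt_sr_detected <= t.dbt_dr_detected):
        fail("DBT single-reading detected not nested in double-reading detected")
    non_cancers = t.n_exams - t.cancers
    for sr, dr, label in (
        (t.sm_sr_fp, t.sm_dr_fp, "SM"),
        (t.dbt_sr_fp, t.dbt_dr_fp, "DBT"),
    ):
        if not (0 <= sr <= dr <= non_cancers):
            fail(f"{label} false-positive counts violate nesting or band size")


def _check_targets() -> None:
    for name, t in BAND_TARGETS.items():
        _check_band(name, t)
    total = {
        "exams": sum(t.n_exams for t in BAND_TARGETS.values()),
        "cancers": sum(t.cancers for t in BAND_TARGETS.values()),
        "sm_dr": sum(t.cancers_sm_dr for t in BAND_TARGETS.values()),
        "dbt_dr": sum(t.cancers_dbt_dr for t in BAND_TARGETS.values()),
    }
    expected = {
        "exams": N_EXAMS,
        "cancers": REFERENCE_CANCERS,
        "sm_dr": SM_DR_DETECTABLE,
        "dbt_dr": DBT_DR_DETECTABLE,
    }
    if total != expected:
        raise FixtureConsistencyError(
            f"band totals {total} do not match global totals {expected}"
        )


def _build_band(name: str, t: BandTargets, id_offset: int) -> pd.DataFrame:
    """Assign flags to the records of one band.

    Cancers are laid out first, ordered so that nested prefix assignment
    hits every target: SM-DR-detectable cancers occupy a prefix and
    DBT-DR-detectable cancers a suffix of the cancer block, overlapping in
    the middle by exactly the required amount.  Single-reading recalls are
    prefixes (SM) / suffixes (DBT) of the corresponding double-reading
    sets.  False positives are leading non-cancer records per modality, so
    SM and DBT false positives overlap maximally; cross-modality overlap
    is not constrained by any printed count.
    """
    n = t.n_exams
    cancer = np.zeros(n, dtype=bool)
    cancer[: t.cancers] = True

    sm_dr = np.zeros(n, dtype=bool)
    sm_sr = np.zeros(n, dtype=bool)
    dbt_dr = np.zeros(n, dtype=bool)
    dbt_sr = np.zeros(n, dtype=bool)

    # cancer block: [0, cancers_sm_dr) detectable by SM-DR,
    # [cancers - cancers_dbt_dr, cancers) detectable by DBT-DR
    sm_dr[: t.cancers_sm_dr] = True
    dbt_start = t.cancers - t.cancers_dbt_dr
    dbt_dr[dbt_start : t.cancers] = True
    sm_sr[: t.sm_sr_detected] = True
    dbt_sr[t.cancers - t.dbt_sr_detected : t.cancers] = True

    # non-cancer block: false positives from the front
    nc0 = t.cancers
    sm_dr[nc0 : nc0 + t.sm_dr_fp] = True
    sm_sr[nc0 : nc0 + t.sm_sr_fp] = True
    dbt_dr[nc0 : nc0 + t.dbt_dr_fp] = True
    dbt_sr[nc0 : nc0 + t.dbt_sr_fp] = True

    return pd.DataFrame(
        {
            "exam_id": [f"fx{idx:05d}" for idx in range(id_offset, id_offset + n)],
            "ai_score": np.full(n, BAND_SCORES[name]),
            "cancer": cancer,
            "recall_sm_sr": sm_sr,
            "recall_sm_dr": sm_dr,
            "recall_dbt_sr": dbt_sr,
            "recall_dbt_dr": dbt_dr,
        }
    )


def build_fixture_cohort() -> CohortTable:
    """Construct the deterministic 14,772-record fixture cohort.

    Evaluating any of the four triage workflows at thresholds 5 and 7 on
    the returned cohort reproduces every cell of the published per-stratum
    tables; the cancer totals are 135 reference cancers, 95 detectable by
    SM double reading and 127 by DBT double reading.
    """
    _check_targets()
    frames = []
    offset = 0
    for name in ("A", "B", "C"):
        t = BAND_TARGETS[name]
        frames.append(_build_band(name, t, offset))
        offset += t.n_exams
    df = pd.concat(frames, ignore_index=True)
    return CohortTable(df, provenance="fixture")
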