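"""Cohort container and on-disk format.

A screening cohort is a table with one row per screened woman holding the
examination-level AI risk score (continuous, 0-10), the cancer reference
status, and the final recall outcome under each of the four reading arms:

* ``recall_sm_sr``  -- synthetic mammography, single reading
* ``recall_sm_dr``  -- synthetic mammography, double reading
* ``recall_dbt_sr`` -- tomosynthesis, single reading
* ``recall_dbt_dr`` -- tomosynthesis, double reading

Single-reading recall is modelled as "flagged by the first reader AND
recalled at the consensus meeting", so within each modality the
single-reading recalls are a subset of the double-reading recalls.  This
nesting is enforced as a table invariant.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the cohort CSV.
COHORT_COLUMNS = (
    "exam_id",
    "ai_score",
    "cancer",
    "recall_sm_sr",
    "recall_sm_dr",
    "recall_dbt_sr",
    "recall_dbt_dr",
)

BOOL_COLUMNS = COHORT_COLUMNS[2:]

SCORE_MIN = 0.0
SCORE_MAX = 10.0


class CohortError(ValueError):
    """Raised when a cohort table violates its invariants."""


class SchemaError(CohortError):
    """Raised when a cohort CSV is missing required columns."""


@dataclass
class CohortTable:
    """An ordered collection of examination records.

    Parameters
    ----------
    frame
        DataFrame with the columns of :data:`COHORT_COLUMNS`.  Boolean
        columns are coerced to ``bool``, the score to ``float``.
    provenance
        Free-text tag recording where the table came from (generator
        parameters and seed, or ``"fixture"``).
    """

    frame: pd.DataFrame
    provenance: str = ""
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"cohort table is missing columns: {missing}")
        df = self.frame.loc[:, list(COHORT_COLUMNS)].copy()
        df["ai_score"] = df["ai_score"].astype(float)
        for col in BOOL_COLUMNS:
            df[col] = df[col].astype(bool)
        df = df.reset_index(drop=True)
        self.frame = df
        self._check_invariants()
        self._validated = True

    def _check_invariants(self) -> None:
        df = self.frame
        if len(df) == 0:
            raise CohortError("cohort table must be non-empty")
        if df["exam_id"].duplicated().any():
            dup = df.loc[df["exam_id"].duplicated(), "exam_id"].iloc[0]
            raise CohortError(f"duplicate exam_id: {dup!r}")
        scores = df["ai_score"].to_numpy()
        if not np.all((scores >= SCORE_MIN) & (scores <= SCORE_MAX)):
            bad = df.loc[(scores < SCORE_MIN) | (scores > SCORE_MAX), "exam_id"].iloc[0]
            raise CohortError(f"ai_score outside [0, 10] for exam {bad!r}")
        for sr, dr in (("recall_sm_sr", "recall_sm_dr"), ("recall_dbt_sr", "recall_dbt_dr")):
            violates = df[sr] & ~df[dr]
            if violates.any():
                bad = df.loc[violates, "exam_id"].iloc[0]
                raise CohortError(
                    f"{sr} set without {dr} for exam {bad!r}: single-reading "
                    "recall requires the consensus recall that defines "
                    "double-reading recall"
                )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_cancers(self) -> int:
        return int(self.frame["cancer"].sum())

    def detected_count(self, arm_column: str) -> int:
        """Cancers recalled under the arm whose recall column is given."""
        df = self.frame
        return int((df["cancer"] & df[arm_column]).sum())

    def equals(self, other: "CohortTable") -> bool:
        return self.frame.equals(other.frame)


def write_cohort(cohort: CohortTable, destination: str | os.PathLike | io.TextIOBase) -> None:
    """Write a cohort to CSV (UTF-8, header row, 0/1 booleans, full-precision scores)."""
    df = cohort.frame.copy()
    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(int)
    df.to_csv(destination, index=False, float_format="%.17g")


def read_cohort(source: str | os.PathLike | io.TextIOBase, provenance: str | None = None) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    SchemaError
        If required columns are missing.
    CohortError
        If any row fails to parse or an invariant is violated.
    """
    try:
        df = pd.read_csv(source, dtype={"exam_id": str})
    except pd.errors.ParserError as exc:  # malformed row; pandas reports the line
        raise CohortError(f"malformed cohort CSV: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV is missing columns: {missing}")
    for col in BOOL_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | ~values.isin((0, 1))
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise CohortError(f"column {col!r}: non-0/1 value at line {line}")
        df[col] = values.astype(bool)
    scores = pd.to_numeric(df["ai_score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.isna().idxmax()) + 2
        raise CohortError(f"column 'ai_score': non-numeric value at line {line}")
    df["ai_score"] = scores
    if provenance is None:
        provenance = f"read from {getattr(source, 'name', source)}"
    return CohortTable(df, provenance=provenance)
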