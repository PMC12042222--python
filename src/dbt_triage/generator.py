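"""Stochastic synthetic-cohort generator.

Emulates the statistical structure of a paired-reading DBT screening
population: ~14,772 examinations, 135 reference cancers of which 95 are
detectable by SM/DM double reading and 127 by DBT double reading, and an
AI-score distribution with ~30% of examinations at score >= 5 and ~22% at
score >= 7.

Modelling choices
-----------------
* Cancer membership and the two detectable sets are assigned by exact
  sampling without replacement, not Bernoulli draws, so the global totals
  are hit exactly in every realisation.
* AI scores are Beta distributions scaled to [0, 10], one per outcome
  class (non-cancer, DBT-detectable cancer, cancer detectable only on
  SM/DM).  The real score distribution is unpublished; Beta mixtures are
  the simplest family with bounded support that can match the printed
  stratum fractions.
* Double-reading recall of a cancer equals membership of the modality's
  detectable set.  Single-reading recall is double-reading recall thinned
  by an independent Bernoulli(p_sr_given_dr) per modality — the first
  reader's flag among the flags that led to a consensus recall.
* False-positive recalls are per-arm Bernoulli draws at the double-reading
  level with piecewise-constant, score-band-dependent rates (rates rise
  with score), thinned to single reading the same way.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

from .records import CohortTable

#: Score-band edges for the piecewise-constant false-positive rates.
FP_BAND_EDGES = (5.0, 7.0)


class ValidationError(ValueError):
    """Invalid generator parameters."""


class CalibrationError(ValueError):
    """Calibration targets infeasible or not met within tolerance."""


class ScaledBeta(BaseModel):
    """A Beta(a, b) distribution scaled to the score range [0, 10]."""

    model_config = ConfigDict(frozen=True)

    a: float = Field(gt=0)
    b: float = Field(gt=0)

    def sf(self, score: float) -> float:
        """P(score' >= score) under this component."""
        return float(stats.beta.sf(score / 10.0, self.a, self.b))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return 10.0 * rng.beta(self.a, self.b, size=n)


class BandRates(BaseModel):
    """Per-band probabilities over the bands (<5, 5-7, >=7)."""

    model_config = ConfigDict(frozen=True)

    low: float = Field(ge=0, le=1)
    mid: float = Field(ge=0, le=1)
    high: float = Field(ge=0, le=1)

    def lookup(self, scores: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(FP_BAND_EDGES, scores, side="right")
        return np.asarray([self.low, self.mid, self.high])[idx]


class GeneratorParams(BaseModel):
    """Parameters of the synthetic-cohort generator.

    Defaults reproduce the study structure: cohort size, cancer totals,
    score distributions calibrated to the 30%/22% stratum fractions, and
    recall probabilities matched to the published per-stratum recall and
    detection counts.
    """

    model_config = ConfigDict(frozen=True)

    n_exams: int = Field(default=14_772, gt=0)
    n_cancers_combined: int = Field(default=135, ge=0)
    n_cancers_dm_dr: int = Field(default=95, ge=0)
    n_cancers_dbt_dr: int = Field(default=127, ge=0)
    score_dist_noncancer: ScaledBeta = ScaledBeta(a=0.21348, b=0.47443)
    score_dist_cancer_dbt: ScaledBeta = ScaledBeta(a=0.50691, b=0.054233)
    score_dist_cancer_sm_only: ScaledBeta = ScaledBeta(a=0.27978, b=0.096845)
    p_sr_given_dr_sm: float = Field(default=0.74, ge=0, le=1)
    p_sr_given_dr_dbt: float = Field(default=0.87, ge=0, le=1)
    fp_rate_sm_dr: BandRates = BandRates(low=0.013195, mid=0.024555, high=0.030168)
    fp_rate_dbt_dr: BandRates = BandRates(low=0.015523, mid=0.029636, high=0.055891)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorParams":
        if self.n_cancers_combined > self.n_exams:
            raise ValueError("n_cancers_combined exceeds n_exams")
        for name in ("n_cancers_dm_dr", "n_cancers_dbt_dr"):
            if getattr(self, name) > self.n_cancers_combined:
                raise ValueError(f"{name} exceeds n_cancers_combined")
        if self.n_cancers_dm_dr + self.n_cancers_dbt_dr < self.n_cancers_combined:
            raise ValueError(
                "n_cancers_dm_dr + n_cancers_dbt_dr must cover n_cancers_combined "
                "(every reference cancer is detectable by at least one modality)"
            )
        return self

    def mixture_sf(self, score: float) -> float:
        """P(score' >= score) under the population mixture, analytically."""
        w_dbt = self.n_cancers_dbt_dr / self.n_exams
        w_smo = (self.n_cancers_combined - self.n_cancers_dbt_dr) / self.n_exams
        w_non = 1.0 - self.n_cancers_combined / self.n_exams
        return (
            w_non * self.score_dist_noncancer.sf(score)
            + w_dbt * self.score_dist_cancer_dbt.sf(score)
            + w_smo * self.score_dist_cancer_sm_only.sf(score)
        )


def generate_cohort(params: GeneratorParams, seed: int | None = None) -> CohortTable:
    """Draw one synthetic cohort.

    All randomness flows from a single ``numpy`` Generator seeded with
    ``seed`` (falling back to ``params.seed``); identical inputs give
    identical cohorts record-for-record.
    """
    try:
        params = GeneratorParams.model_validate(params)
    except Exception as exc:
        raise ValidationError(str(exc)) from exc
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    n = params.n_exams
    n_cancer = params.n_cancers_combined
    n_dm = params.n_cancers_dm_dr
    n_dbt = params.n_cancers_dbt_dr
    n_both = n_dm + n_dbt - n_cancer
    n_dm_only = n_cancer - n_dbt
    n_dbt_only = n_cancer - n_dm

    cancer = np.zeros(n, dtype=bool)
    cancer[:n_cancer] = True
    # cancer block layout: [dm-only | both | dbt-only]; detectable sets are
    # exact by construction
    sm_detectable = np.zeros(n, dtype=bool)
    sm_detectable[: n_dm_only + n_both] = True
    dbt_detectable = np.zeros(n, dtype=bool)
    dbt_detectable[n_dm_only : n_cancer] = True

    scores = np.empty(n, dtype=float)
    scores[dbt_detectable] = params.score_dist_cancer_dbt.rvs(n_dbt, rng)
    n_smo = n_dm_only
    scores[:n_smo] = params.score_dist_cancer_sm_only.rvs(n_smo, rng)
    scores[n_cancer:] = params.score_dist_noncancer.rvs(n - n_cancer, rng)
    np.clip(scores, 0.0, 10.0, out=scores)

    # double-reading recalls: detectability for cancers, score-banded
    # false-positive draws for non-cancers
    recall_sm_dr = sm_detectable.copy()
    recall_dbt_dr = dbt_detectable.copy()
    noncancer = ~cancer
    nc_scores = scores[noncancer]
    recall_sm_dr[noncancer] = rng.random(n - n_cancer) < params.fp_rate_sm_dr.lookup(nc_scores)
    recall_dbt_dr[noncancer] = rng.random(n - n_cancer) < params.fp_rate_dbt_dr.lookup(nc_scores)

    # single reading: first-reader flag AND the shared consensus recall
    recall_sm_sr = recall_sm_dr & (rng.random(n) < params.p_sr_given_dr_sm)
    recall_dbt_sr = recall_dbt_dr & (rng.random(n) < params.p_sr_given_dr_dbt)

    perm = rng.permutation(n)
    df = pd.DataFrame(
        {
            "exam_id": [f"s{idx:06d}" for idx in range(n)],
            "ai_score": scores[perm],
            "cancer": cancer[perm],
            "recall_sm_sr": recall_sm_sr[perm],
            "recall_sm_dr": recall_sm_dr[perm],
            "recall_dbt_sr": recall_dbt_sr[perm],
            "recall_dbt_dr": recall_dbt_dr[perm],
        }
    )
    provenance = (
        f"generated: n_exams={n} cancers={n_cancer}/{n_dm}/{n_dbt} seed={seed}"
    )
    return CohortTable(df, provenance=provenance)


class CalibrationTargets(BaseModel):
    """Quantile and stratum-detection constraints for score calibration.

    ``quantile_constraints`` are (threshold, fraction of all examinations
    with score >= threshold) pairs; fractions must be non-increasing in
    threshold.  ``stratum_detection_constraints`` are (threshold, arm,
    fraction of arm-detectable cancers with score >= threshold) triples;
    only the ``"dbt_dr"`` arm is calibratable (its detectable-class score
    distribution is a free component of the mixture).
    """

    model_config = ConfigDict(frozen=True)

    quantile_constraints: tuple[tuple[float, float], ...] = ()
    stratum_detection_constraints: tuple[tuple[float, str, float], ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "CalibrationTargets":
        pairs = sorted(self.quantile_constraints)
        for thr, frac in pairs:
            if not (0.0 <= thr <= 10.0):
                raise ValueError(f"threshold {thr} outside [0, 10]")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for (t1, f1), (t2, f2) in zip(pairs, pairs[1:]):
            if t2 > t1 and f2 > f1:
                raise ValueError(
                    f"fractions must be non-increasing in threshold: "
                    f"P(>= {t2}) = {f2} > P(>= {t1}) = {f1}"
                )
        for thr, arm, frac in self.stratum_detection_constraints:
            if arm != "dbt_dr":
                raise ValueError(f"unsupported calibration arm {arm!r}")
            if not (0.0 <= thr <= 10.0 and 0.0 <= frac <= 1.0):
                raise ValueError(f"invalid detection constraint ({thr}, {arm}, {frac})")
        return self


#: The study's printed stratum fractions and DBT-detectable cancer counts.
DEFAULT_TARGETS = CalibrationTargets(
    quantile_constraints=((5.0, 0.30), (7.0, 0.22)),
    stratum_detection_constraints=((5.0, "dbt_dr", 116 / 127), (7.0, "dbt_dr", 112 / 127)),
)


def _fit_component(
    targets: Sequence[tuple[float, float]],
    residual_of,  # (a, b, threshold, target) -> residual
    x0: tuple[float, float],
) -> ScaledBeta:
    def fun(log_ab: np.ndarray) -> np.ndarray:
        a, b = np.exp(log_ab)
        return np.array([residual_of(a, b, thr, tgt) for thr, tgt in targets])

    sol = optimize.least_squares(fun, np.log(x0), method="trf")
    a, b = np.exp(sol.x)
    return ScaledBeta(a=a, b=b)


def calibrate_scores(
    targets: CalibrationTargets,
    params: GeneratorParams,
    tol: float = 0.005,
) -> GeneratorParams:
    """Fit score-distribution parameters to the calibration targets.

    The non-cancer component is adjusted so the analytic mixture matches
    each quantile constraint; the DBT-detectable cancer component is
    adjusted to any stratum-detection constraints.  Residuals are checked
    on the analytic mixture survival function (no sampling); a worst
    residual above ``tol`` raises :class:`CalibrationError`.
    """
    targets = CalibrationTargets.model_validate(targets)
    out = params

    det = [(thr, frac) for thr, _arm, frac in targets.stratum_detection_constraints]
    if det:
        comp = _fit_component(
            det,
            lambda a, b, thr, tgt: float(stats.beta.sf(thr / 10.0, a, b)) - tgt,
            (params.score_dist_cancer_dbt.a, params.score_dist_cancer_dbt.b),
        )
        out = out.model_copy(update={"score_dist_cancer_dbt": comp})

    if targets.quantile_constraints:
        w_non = 1.0 - out.n_cancers_combined / out.n_exams
        if w_non <= 0:
            raise CalibrationError("no non-cancer mass to calibrate")

        def residual(a: float, b: float, thr: float, tgt: float) -> float:
            trial = out.model_copy(update={"score_dist_noncancer": ScaledBeta(a=a, b=b)})
            return trial.mixture_sf(thr) - tgt

        comp = _fit_component(
            targets.quantile_constraints,
            residual,
            (params.score_dist_noncancer.a, params.score_dist_noncancer.b),
        )
        out = out.model_copy(update={"score_dist_noncancer": comp})

    residuals = [
        (thr, abs(out.mixture_sf(thr) - frac)) for thr, frac in targets.quantile_constraints
    ] + [
        (thr, abs(out.score_dist_cancer_dbt.sf(thr) - frac))
        for thr, _arm, frac in targets.stratum_detection_constraints
    ]
    if residuals:
        worst_thr, worst = max(residuals, key=lambda t: t[1])
        if worst > tol:
            raise CalibrationError(
                f"calibration failed: worst residual {worst:.4f} at threshold "
                f"{worst_thr} exceeds tolerance {tol}"
            )
    return out
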