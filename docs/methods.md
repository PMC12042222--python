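# Methods

## Problem and model

In tomosynthesis (DBT)-based breast screening, every woman's examination
yields both the full DBT stack and a synthetic 2D mammogram (SM) that is
much faster to read. An examination-level AI risk score in [0, 10]
triages each woman: below a threshold *t* only the SM is read (low-risk
arm), at or above *t* the DBT is read (high-risk arm). Each arm uses
single reading (SR) or double reading (DR), giving four workflow
combinations. The package quantifies, as functions of *t*: reading
workload, recalls, false-positive recalls, and detected cancers, plus a
clinic-level staffing model.

Workload is measured in reading-time equivalents: one single SM read = 1
unit, one DBT read = *r* units, double reading doubles the per-exam
units. The default *r* = 2 reflects reported DBT reading times roughly
twice those of 2D mammography; *r* = 1.7 is a less conservative
alternative exposed as a parameter. Workload is kept real-valued (it is
non-integer when *r* = 1.7) and only rounded at the reporting layer.

Recall semantics: double-reading recall is the consensus decision;
single-reading recall requires the first reader's flag *and* the same
consensus recall, so SR recalls are nested within DR recalls per
modality. A *reference cancer* is one detectable by combined SM and DBT
double reading (135 in the default cohort structure, of which 95 are
detectable by SM/2D double reading and 127 by DBT double reading). A
cancer counts as detected by a workflow when the arm its score assigns
it to recalls it; reference cancers are attributed to the stratum their
score places them in, and a cancer in the SM stratum counts as
non-detected unless the SM arm recalls it. Consequently
`detected + non_detected = reference_cancers` in every evaluation, and
the engine requires the evaluated cohort's cancer set to *be* the
reference set (a larger external reference count would have no stratum
to sit in).

Stratum boundary convention: the DBT stratum is the half-open interval
[*t*, 10]; ties at the threshold go to DBT ("score 5 or higher").

## Derived quantities and rounding

`summarize_vs_baseline` reports percent detection gain over a baseline
arm (default: the 95 cancers of uniform 2D double reading), percent of
the 127 DBT-detectable cancers found, percent workload change versus a
baseline workload (default 2 units/exam, i.e. uniform 2D double
reading), and detection rate per 1000 screened. Percentages are rounded
half-up (away from zero) to integers; rates per 1000 to two decimals.
The closed-form workload-neutral high-risk fraction solves
a(1−p) + b·p = baseline; for SR-SM + DR-DBT at r = 2 this gives
p* = 1/3, and the neutral threshold is the (1−p*) score quantile.

## The deterministic fixture cohort

The study population is not deposited, but the two published per-stratum
tables (thresholds 5 and 7, all four workflows, six columns each) plus
the global cancer totals over-determine a three-band integer structure:

| band | scores | exams | cancers | SM-DR detectable | DBT-DR detectable |
|------|--------|-------|---------|------------------|-------------------|
| A | < 5 | 10,320 | 13 | 9 | 11 |
| B | 5–7 | 1,185 | 4 | 3 | 4 |
| C | ≥ 7 | 3,267 | 118 | 83 | 112 |

Band B is the difference of the two tables' strata; band-level recall
and false-positive counts per arm follow the same differencing. The
builder lays records out per band — SM-detectable cancers as a prefix of
the cancer block, DBT-detectable as a suffix, overlapping by exactly the
count forced by the union constraint; SR recalls as nested prefixes and
suffixes; false positives as leading non-cancer records per modality —
and a consistency check (coverage, nesting, band sizes, global totals)
runs before construction and aborts with a diagnostic if the targets are
ever edited into infeasibility.

A few counts are not pinned by any printed cell because their band is
never read with that modality at thresholds 5 or 7: SM recalls in band C
(SR detected 55 of 83, SR/DR false positives 70/95) and DBT recalls in
band A (SR detected 9 of 11, SR/DR false positives 120/160). They were
fixed once at values continuing the observed rate gradients and only
affect threshold sweeps away from {5, 7}. Representative scores are band
midpoints 2.5 / 6.0 / 8.5; any values inside the half-open intervals are
equivalent at the two analysed thresholds. Because scores sit at three
atoms, the fixture's sweep curves are step functions: counts at
thresholds 5 and 7 are exact, curve shape between them is not meaningful
(the score placement of individual cancers within bands is unknowable
from the printed tables).

## The stochastic generator

`generate_cohort` emulates the same structure with sampling. Cancer
membership and the two detectable sets are assigned by exact counts
(n = 14,772; 135/95/127 by default), never Bernoulli, so the totals hold
in every realisation. AI scores are Beta distributions scaled to
[0, 10], one per outcome class: non-cancers, DBT-detectable cancers, and
cancers detectable only on SM. The true score distributions are
unpublished; Beta components are the simplest bounded-support family
able to match the published quantiles. Defaults were solved analytically
from those quantiles: the population mixture puts 30% of examinations at
score ≥ 5 and 22% at ≥ 7, and the DBT-detectable cancer component puts
116/127 at ≥ 5 and 112/127 at ≥ 7 (the fitted non-cancer component is
U-shaped, consistent with a score designed to spread a screening
population across its range). `calibrate_scores` re-fits these
components to arbitrary feasible targets by least squares on the
analytic mixture survival function (no sampling) and raises with the
worst residual if the fit misses any target by more than 0.005.

Double-reading recall of a cancer equals detectable-set membership.
Single reading thins double reading by one Bernoulli probability per
modality (SM 0.74, DBT 0.87), a compromise between the published
detection ratios (e.g. 105/116 ≈ 0.91 for DBT at threshold 5) and
false-positive ratios (176/211 ≈ 0.83) which a single per-modality
probability cannot both match exactly; generated per-stratum SR counts
are therefore approximate where the fixture's are exact. False positives
are per-arm Bernoulli draws at the DR level with piecewise-constant
rates over the three score bands (rising with score, matched to the
fixture's band rates), thinned to SR the same way. All randomness flows
from a single seeded NumPy generator; identical (params, seed) give
identical cohorts.

What the generator does not emulate: inter-reader correlation beyond the
nested first-reader/consensus rule, interval cancers and longitudinal
follow-up, score–size or score–density structure within a class, and any
dependence of false positives on cancer prevalence in the neighbourhood
of the threshold. Tests passing on synthetic cohorts therefore validate
the accounting machinery and the calibrated marginals, not the clinical
realism of any particular score model.

## Clinic capacity model

`estimate_fte` converts a workflow evaluation into full-time-equivalent
radiologists for an example clinic: annual screen-reading seconds scale
the cohort's stratum shares to the clinic's annual volume at
40 s per SM/2D read and 80 s per DBT read (per reader); recall workup
and symptomatic referrals share one capacity constant (20 women per
radiologist-day); the referral flow is independent of the screening
workflow by assumption. The working calendar is not fully specified by
the example (only 40-hour weeks are); defaults of 45 working weeks
(1,800 h) and 225 working days per year are package choices, exposed as
parameters, and cancel out of any between-workflow comparison. FTEs are
reported unrounded; staffing ceilings are left to the caller.

## Problem sizes and numerics

All worked-example computations run on the 14,772-record fixture in
milliseconds; threshold sweeps use a 0–10 grid at step 0.05 (201 points)
via a sort-plus-cumulative-sum pass rather than per-threshold rescans.
Property tests use random cohorts of up to 1,000 records (100
replicates for the independent per-record oracle) and one 100,000-exam
cohort for calibration recovery, which is checked within three binomial
standard errors of the target fractions with the cancer counts scaled
proportionally so the mixture weights match the calibrated cohort.
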