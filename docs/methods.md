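# Methods

## The screening problem

Retinopathy of prematurity develops in two phases: arrested retinal
vascularization after pre-term birth, then VEGF-driven abnormal
vasoproliferation. Serum IGF1 participates in both: persistently low levels
in the third week of life mark infants at risk of developing ROP, while a
rapid rise between weeks 3 and 5 accompanies progression to the
proliferative form. The screening rule studied here exploits this: below the
mandatory thresholds (30 + 0 weeks gestation and/or 1,250 g — or 28 + 0
weeks / 1,100 g in the extended variant) every infant is examined serially;
above them, serial exams are indicated only when a logistic model in week-3
IGF1 and early neonatal sepsis predicts a ROP probability strictly above
30%. Low-risk infants get one confirmation exam at 40 weeks postmenstrual
age. All "<" thresholds and the "exceeds 30%" rule are strict inequalities;
the AAP comparator's "≤ 1,500 g / ≤ 30 weeks" are non-strict, following the
printed symbols. Gestational age is decimal weeks; the CLI accepts `W+D` and
converts it as W + D/7.

## Synthetic cohorts

No patient-level data are distributed with the source study, so every
downstream stage runs on synthetic cohorts whose defaults encode the
reported structure of the prospective validation stratum (n = 153, 30–32
weeks, 1,250–1,500 g):

| parameter | default | basis |
|---|---|---|
| `high_risk_frac` | 0.209 | reported high-risk fraction 32/153 |
| `igf1_w3_mean_by_risk` | (51, 30.48) ng/ml | reported group means |
| `igf1_w3_sd` | 5 ng/ml | not reported; chosen once so the strata stay separable, consistent with the strongly significant group contrast |
| `sepsis_rate_by_risk` | (0.066, 0.156) | reported prevalences |
| `pct_increase_mean_by_grade` | (14.10, 21.47, 28.97) % | reported grade means |
| `pct_increase_sd` | 20 % | not reported; order of magnitude implied by the width of the reported proliferative CI (−1.18 to 59.13) |
| `p_proliferative` | 0.2 | P(proliferative \| ROP); the validation cohort contained no proliferative cases, so this is a free parameter kept small |
| `ga_range_weeks`, `bw_range_g` | (30, 32), (1250, 1500) | enrolment box |
| `ga_bw_coupling` | 0.3 | mild positive GA–weight correlation |
| `missing_w5_rate` | 0 | complete trajectories by default |

Generation order: latent risk stratum ~ Bernoulli(`high_risk_frac`); GA
uniform in its range; weight shares the GA quantile with weight
`ga_bw_coupling` (uniform marginal, positive correlation); IGF1 ~ normal with
the stratum mean, truncated at 1 ng/ml; sepsis ~ Bernoulli with the stratum
rate; ROP ~ Bernoulli of the generative logistic probability given IGF1 and
sepsis; grade = proliferative with probability `p_proliferative` given ROP;
week-5 IGF1 = IGF1₃w·(1 + Δ/100) with Δ normal around the grade mean,
truncated so the result stays positive. Length and head circumference are
carried as inert optional columns. One `SeedSequence` per cohort is split
into named per-stage streams, so identical parameters give bit-identical
cohorts and adding a stage cannot perturb earlier draws.

The enrolment tables report a mean low-risk birth weight of 1,606 g inside a
cohort described as 1,250–1,500 g; the generator exposes both the GA and the
weight range and takes no position on that inconsistency — weights are drawn
inside the configured box.

What the simulator does *not* emulate: real IGF1 distributions are skewed
and correlated with gestational age and nutrition; sepsis is a process, not
a coin flip; and the oxygen/ventilation/transfusion covariates are inert
columns, not causal factors. Passing tests therefore demonstrate the
correctness and calibration of the pipeline under the stated generative
model, not clinical performance on real infants.

## Two models, deliberately distinct

The original probability-curve coefficients were never published, and the
published numbers constrain them only loosely. Two facts cannot be served by
a single logistic: infants flagged high-risk (predicted probability > 30%)
showed only 9.4% observed ROP, so the generative incidence in the low-IGF1
stratum must be near 9–10%, far below the 30% flag line. The package
therefore ships:

- `GENERATIVE_TRUTH_MODEL` (β₀ = 3.48, β₁ = −0.19, β₂ = 0.8): used by the
  simulator; gives ≈ 9–12% ROP in the low-IGF1 stratum, a few per mille in
  the high-IGF1 stratum, and odds roughly doubled by sepsis.
- `REFERENCE_SCREENING_MODEL` (β₀ = 18 + logit 0.3 ≈ 17.15, β₁ = −0.45,
  β₂ = 0.9): a *reconstruction* of the screening score, calibrated so its
  30% contour falls at 40 ng/ml for non-septic infants (42 ng/ml for septic
  ones), midway between the two reported stratum means. Under the default
  cohort this flags ≈ 21–22% of infants, matching the reported 20.9%
  high-risk fraction. It is labelled reconstructed wherever serialized and
  is a default, not a claim about the unpublished parameters.

Whether the reported "discriminative efficacy of 87.7%" is an AUC or some
other index is not defined in the source; it is not asserted as a target
anywhere. The acceptance script reports the simulated AUC of the week-3
IGF1 level for reference.

## Fitting: IRLS with guard rails

`IRLSLogisticRegression` maximizes the Bernoulli likelihood by Newton/IRLS
from an all-zero start: working response z = η + (y − μ)/w with w = μ(1−μ),
normal equations XᵀWX β = XᵀWz with a ridge jitter of 1e-8 on the diagonal,
and step-halving whenever a full Newton step would decrease the
log-likelihood — making the log-likelihood path monotone by construction.
Convergence is a max absolute coefficient update below 1e-8, capped at 100
iterations. Standard errors come from the inverse Fisher information at the
optimum. (Quasi-)complete separation is detected when every record is fitted
essentially perfectly (|y − μ| < 1e-3 everywhere) while the linear predictor
saturates; such fits are flagged (`separation=True, converged=False`) and
refuse to predict, rather than returning divergent coefficients. Tests
cross-check the estimates against an independent ML implementation
(statsmodels) to 1e-6.

## ROC and its U-statistic identity

The empirical ROC steps through the distinct score values, grouping ties at
a single threshold; AUC is the trapezoidal integral. With ties grouped this
way the AUC equals the Mann–Whitney statistic (pairs won plus half the
ties) divided by n₊·n₋ exactly, which the tests verify against a brute-force
pairwise count at 1e-12 on random instances up to n = 200.

## Diagnostic metrics

The validation 2×2 table crosses the high-/low-risk tiers with observed ROP
(any grade); mandatory-tier infants are excluded because the clinical
validation concerns only infants above both mandatory thresholds.
Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), PPV = tp/(tp+fp),
NPV = tn/(tn+fn), each with a Clopper–Pearson exact 95% CI (chosen because
the validation counts are small and NPV sits on the 100% boundary; the
source reports no intervals, so these are supplementary, never compared to
printed values). Zero-denominator metrics are marked undefined instead of
raising or fabricating. Display rounding is half-up to one decimal in
percent (so 9.375% prints as 9.4%), computed via decimal arithmetic; the
screened/excluded fractions are formed in rational arithmetic so they are
exactly complementary before rounding. One reported value is irreproducible
from its own counts: the retrospective specificity prints as 77.1% while
151/196 = 77.04% → 77.0%; the package reproduces the counts-derived value.

## Trajectory statistics and tests

The percentage increase 100·(IGF1₅w − IGF1₃w)/IGF1₃w is summarized per ROP
grade by mean, symmetric t-interval mean ± t₀.₉₇₅,ₙ₋₁·s/√n (the reported
proliferative interval is symmetric about its mean, consistent with this
choice), and quartiles by linear interpolation. Grades with fewer than two
complete trajectories are marked unavailable; infants lacking the week-5
measurement are excluded and counted.

Two-group comparisons: Welch's t by default when a Shapiro–Wilk gate
(α = 0.05 per group) accepts normality in `auto` mode (the t-variant used in
the source is unstated; Welch is the safer default under unequal group
sizes, and pooled Student's t is available), Mann–Whitney U otherwise. The
Mann–Whitney p-value is exact while min(n) ≤ 8 — the tie-free exact
distribution, or full enumeration of group assignments when ties are present
and the enumeration is tractable — and a tie- and continuity-corrected
normal approximation beyond that. χ² is Pearson without continuity
correction by default (Yates available by flag; the source's variant is
unstated), and one-way ANOVA uses the standard F test, with the degenerate
all-constant case defined as F = 0, p = 1.

## Problem sizes and tolerances

Statistical checks run at sizes where 3-standard-error bands are tight
enough to be meaningful yet cheap: 10,000 infants for calibration and
monotonicity checks, 50,000 × 20 replicates for coefficient recovery, 5,000
per grade for trajectory recovery, exact enumeration up to group sizes
(6, 6). Exact identities (AUC/U, metric definitions, closed-form CIs) are
asserted at 1e-10 to 1e-12; agreement with independent implementations at
1e-6 or better.

## Known limitations

- The reference screening model is a calibrated reconstruction; only its
  induced high-risk fraction, not its coefficients, is anchored to reported
  data.
- The simulator's latent two-component mixture reproduces group-conditional
  means, not full covariate distributions, and treats enrolment variables as
  independent of IGF1 within stratum.
- The AAP comparator reduces "unstable clinical evolution or respiratory
  support" to one caller-supplied flag and does not schedule the serial exam
  timetable; the nesting of the validated rule inside AAP screening holds on
  the ≤ 1,500 g enrolment region (above 1,500 g, AAP itself screens only
  unstable infants).
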