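"""Seeded synthetic pre-term cohort generator.

The generator emulates the joint structure of the validation cohort: a latent
high-risk subgroup with depressed week-3 IGF1 and elevated sepsis prevalence,
ROP outcomes drawn from a logistic model in IGF1 and sepsis (so disease
concentrates in low-IGF1 / septic infants), and week-3->5 IGF1 percentage
increases whose mean rises with ROP grade.

Randomness: one integer seed per cohort, split into independent named
sub-streams via ``numpy.random.SeedSequence.spawn``, so adding a stage never
perturbs the draws of earlier stages.  Identical ``CohortParams`` (seed
included) give bit-identical cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import Cohort, CohortParams, InfantRecord, ROP_GRADES

__all__ = ["generate_cohort", "assign_week5_igf1"]

# anthropometric anchors for the inert optional columns (means near the
# 30-32 wk stratum; carried for completeness, causally inert)
_LENGTH_MEAN_CM = 41.2
_LENGTH_SD_CM = 1.8
_HEAD_MEAN_CM = 29.3
_HEAD_SD_CM = 1.2

_STREAMS = (
    "stratum", "ga", "bw", "igf1", "sepsis", "rop", "grade",
    "pct_increase", "missing", "anthro",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _truncated_normal(mean, sd, lower, rng, size=None):
    a = (lower - np.asarray(mean)) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(params: CohortParams) -> Cohort:
    """Draw a cohort of ``params.n`` infants.

    Covariates first (latent stratum, GA, weight, IGF1, sepsis), then the ROP
    grade from ``params.rop_model`` probabilities, then the week-5 IGF1 from
    the grade-conditional percentage-increase law.
    """
    p = params  # validated by pydantic on construction
    n = p.n
    rng = _rngs(p.seed)

    high = rng["stratum"].random(n) < p.high_risk_frac

    ga_lo, ga_hi = p.ga_range_weeks
    u_ga = rng["ga"].random(n)
    ga = ga_lo + (ga_hi - ga_lo) * u_ga

    # weight shares the GA quantile with weight ga_bw_coupling -> mild
    # positive GA-weight correlation inside the enrolment box
    bw_lo, bw_hi = p.bw_range_g
    u_bw = p.ga_bw_coupling * u_ga + (1.0 - p.ga_bw_coupling) * rng["bw"].random(n)
    bw = bw_lo + (bw_hi - bw_lo) * u_bw

    mean_low, mean_high = p.igf1_w3_mean_by_risk
    means = np.where(high, mean_high, mean_low)
    igf1_w3 = _truncated_normal(means, p.igf1_w3_sd, 1.0, rng["igf1"], size=n)

    rate_low, rate_high = p.sepsis_rate_by_risk
    sepsis = (rng["sepsis"].random(n) < np.where(high, rate_high, rate_low)).astype(int)

    prob_rop = expit(p.rop_model.linear_predictor(igf1_w3, sepsis))
    has_rop = rng["rop"].random(n) < prob_rop
    prolif = rng["grade"].random(n) < p.p_proliferative
    grade_idx = np.where(has_rop, np.where(prolif, 2, 1), 0)
    rop_grade = np.array(ROP_GRADES, dtype=object)[grade_idx]

    delta = _truncated_normal(
        np.asarray(p.pct_increase_mean_by_grade)[grade_idx],
        max(p.pct_increase_sd, 1e-12),  # truncnorm needs sd > 0
        -100.0 + 1e-9,                  # keeps igf1_w5 strictly positive
        rng["pct_increase"],
        size=n,
    )
    if p.pct_increase_sd == 0:
        delta = np.asarray(p.pct_increase_mean_by_grade, dtype=float)[grade_idx]
    igf1_w5 = igf1_w3 * (1.0 + delta / 100.0)
    missing = rng["missing"].random(n) < p.missing_w5_rate
    igf1_w5 = np.where(missing, np.nan, igf1_w5)

    anthro = rng["anthro"]
    length = _truncated_normal(_LENGTH_MEAN_CM, _LENGTH_SD_CM, 1.0, anthro, size=n)
    head = _truncated_normal(_HEAD_MEAN_CM, _HEAD_SD_CM, 1.0, anthro, size=n)

    width = len(str(n))
    frame = pd.DataFrame(
        {
            "infant_id": [f"inf{str(i + 1).zfill(width)}" for i in range(n)],
            "ga_weeks": ga,
            "birth_weight_g": bw,
            "length_cm": length,
            "head_circ_cm": head,
            "igf1_w3": igf1_w3,
            "igf1_w5": igf1_w5,
            "sepsis_w3": sepsis,
            "rop_grade": rop_grade,
        }
    )
    return Cohort(frame=frame, params=p)


def assign_week5_igf1(record: InfantRecord, params: CohortParams,
                      rng: np.random.Generator | None = None) -> InfantRecord:
    """Draw a week-5 IGF1 for one infant from the grade-conditional law.

    igf1_w5 = igf1_w3 * (1 + delta/100), delta ~ Normal(mean[grade], sd)
    truncated below so that igf1_w5 stays strictly positive.
    """
    if record.igf1_w3 <= 0:
        raise ValueError("igf1_w3 must be > 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mean = params.pct_increase_mean_by_grade[ROP_GRADES.index(record.rop_grade)]
    if params.pct_increase_sd == 0:
        delta = float(mean)
    else:
        delta = float(
            _truncated_normal(mean, params.pct_increase_sd, -100.0 + 1e-9, rng)
        )
    return record.model_copy(update={"igf1_w5": record.igf1_w3 * (1.0 + delta / 100.0)})
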