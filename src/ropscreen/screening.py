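"""Two-tier screening decision rule, its restricted extension, and the AAP baseline.

The validated rule mandates serial ophthalmological examinations for every
infant below 30 + 0 weeks gestation and/or below 1,250 g at birth.  Infants
above both thresholds are triaged by the risk model: serial exams only when
the predicted ROP probability exceeds 30%; otherwise a single confirmation
exam at 40 weeks postmenstrual age.  The extended variant lowers the
mandatory thresholds to 28 + 0 weeks / 1,100 g.  The AAP comparator screens
everyone at or below 1,500 g or 30 weeks, plus heavier 1,500-2,000 g infants
above 30 weeks with an unstable clinical course.

All boundary conventions are literal: "<" thresholds of the validated and
extended rules are strict, "exceeds 30%" is a strict ">", and the AAP
thresholds printed with "<=" are non-strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cohort import Cohort, InfantRecord
from .risk import LogisticRiskModel, predict_probability

__all__ = [
    "RuleConfig",
    "ScreeningDecision",
    "StratificationResult",
    "RiskTierClassifier",
    "stratify",
    "stratify_cohort",
    "aap_rule",
    "parse_ga_weeks",
]


class RuleConfig(BaseModel):
    """Thresholds of the screening decision rule."""

    model_config = ConfigDict(frozen=True)

    mandatory_ga_weeks: float = Field(gt=0, default=30.0)
    mandatory_bw_g: float = Field(gt=0, default=1250.0)
    probability_cutoff: float = Field(gt=0, lt=1, default=0.30)
    low_risk_exam_pma_weeks: float = Field(gt=0, default=40.0)
    variant: Literal["validated", "extended", "aap"] = "validated"

    @classmethod
    def validated(cls) -> "RuleConfig":
        return cls()

    @classmethod
    def extended(cls) -> "RuleConfig":
        """Proposed restriction: mandatory only below 28 + 0 weeks / 1,100 g."""
        return cls(mandatory_ga_weeks=28.0, mandatory_bw_g=1100.0, variant="extended")


@dataclass(frozen=True)
class ScreeningDecision:
    """Tier assignment for one infant.

    ``screen`` is True exactly for the mandatory and high-risk tiers;
    low-risk infants get a single confirmation exam at
    ``confirmation_exam_pma_weeks`` postmenstrual age instead.
    ``probability`` is absent for the mandatory tier (the model is never
    evaluated there).
    """

    infant_id: str
    tier: Literal["mandatory", "high_risk", "low_risk"]
    screen: bool
    probability: Optional[float] = None
    confirmation_exam_pma_weeks: Optional[float] = None

    def __post_init__(self):
        if self.screen != (self.tier in ("mandatory", "high_risk")):
            raise ValueError("screen flag inconsistent with tier")
        if (self.tier == "low_risk") != (self.confirmation_exam_pma_weeks is not None):
            raise ValueError("confirmation exam scheduled iff tier is low_risk")


@dataclass(frozen=True)
class StratificationResult:
    decisions: list[ScreeningDecision]
    counts: dict[str, int]

    def __iter__(self):
        return iter(self.decisions)

    def __len__(self):
        return len(self.decisions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "infant_id": [d.infant_id for d in self.decisions],
                "tier": [d.tier for d in self.decisions],
                "screen": [int(d.screen) for d in self.decisions],
                "probability": [d.probability for d in self.decisions],
                "confirmation_exam_pma_weeks": [
                    d.confirmation_exam_pma_weeks for d in self.decisions
                ],
            }
        )


def stratify(record: InfantRecord, model: LogisticRiskModel,
             config: RuleConfig | None = None) -> ScreeningDecision:
    """Assign one infant to the mandatory / high-risk / low-risk tier.

    Pure function of its inputs: mandatory iff GA < threshold or weight <
    threshold (inclusive-or, strict); otherwise the model probability decides,
    high-risk iff it strictly exceeds the cutoff.
    """
    config = config or RuleConfig()
    if record.ga_weeks < config.mandatory_ga_weeks or record.birth_weight_g < config.mandatory_bw_g:
        return ScreeningDecision(infant_id=record.infant_id, tier="mandatory", screen=True)
    prob = predict_probability(model, record.igf1_w3, record.sepsis_w3)
    if prob > config.probability_cutoff:
        return ScreeningDecision(
            infant_id=record.infant_id, tier="high_risk", screen=True, probability=prob
        )
    return ScreeningDecision(
        infant_id=record.infant_id,
        tier="low_risk",
        screen=False,
        probability=prob,
        confirmation_exam_pma_weeks=config.low_risk_exam_pma_weeks,
    )


def stratify_cohort(cohort: Cohort, model: LogisticRiskModel,
                    config: RuleConfig | None = None) -> StratificationResult:
    """One decision per record, order preserving, with tier counts attached."""
    config = config or RuleConfig()
    frame = cohort.frame
    decisions: list[ScreeningDecision] = []
    if len(frame):
        mandatory = (
            (frame["ga_weeks"] < config.mandatory_ga_weeks)
            | (frame["birth_weight_g"] < config.mandatory_bw_g)
        ).to_numpy()
        probs = np.full(len(frame), np.nan)
        nonmand = ~mandatory
        if nonmand.any():
            probs[nonmand] = predict_probability(
                model,
                frame.loc[nonmand, "igf1_w3"].to_numpy(),
                frame.loc[nonmand, "sepsis_w3"].to_numpy(),
            )
        ids = frame["infant_id"].to_numpy()
        for i in range(len(frame)):
            if mandatory[i]:
                decisions.append(
                    ScreeningDecision(infant_id=ids[i], tier="mandatory", screen=True)
                )
            elif probs[i] > config.probability_cutoff:
                decisions.append(
                    ScreeningDecision(
                        infant_id=ids[i], tier="high_risk", screen=True,
                        probability=float(probs[i]),
                    )
                )
            else:
                decisions.append(
                    ScreeningDecision(
                        infant_id=ids[i], tier="low_risk", screen=False,
                        probability=float(probs[i]),
                        confirmation_exam_pma_weeks=config.low_risk_exam_pma_weeks,
                    )
                )
    counts = {
        "mandatory": sum(d.tier == "mandatory" for d in decisions),
        "high_risk": sum(d.tier == "high_risk" for d in decisions),
        "low_risk": sum(d.tier == "low_risk" for d in decisions),
    }
    return StratificationResult(decisions=decisions, counts=counts)


def aap_rule(record: InfantRecord, unstable: bool = False) -> bool:
    """AAP baseline: screen iff weight <= 1,500 g or GA <= 30 weeks, or
    1,500-2,000 g with GA > 30 weeks and an unstable clinical course."""
    bw, ga = record.birth_weight_g, record.ga_weeks
    if bw <= 1500.0 or ga <= 30.0:
        return True
    return bool(1500.0 < bw <= 2000.0 and ga > 30.0 and unstable)


class RiskTierClassifier:
    """scikit-learn style wrapper: predicts screening tiers for a cohort frame.

    ``fit`` stores (and sanity-checks) the risk model and rule configuration;
    ``predict`` maps rows of ``[ga_weeks, birth_weight_g, igf1_w3, sepsis_w3]``
    to tier labels.  Full decisions with probabilities and exam schedules come
    from :func:`stratify_cohort`.
    """

    def __init__(self, model: LogisticRiskModel | None = None,
                 config: RuleConfig | None = None):
        self.model = model
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "config": self.config}

    def set_params(self, **params) -> "RiskTierClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "RiskTierClassifier":
        if self.model is None:
            raise ValueError("a LogisticRiskModel is required")
        if not self.model.converged:
            raise ValueError("risk model did not converge")
        self.model_ = self.model
        self.config_ = self.config or RuleConfig()
        self.classes_ = np.array(["low_risk", "high_risk", "mandatory"])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must be (n, 4): ga_weeks, birth_weight_g, igf1_w3, sepsis_w3")
        ga, bw, igf1, sepsis = X.T
        mandatory = (ga < self.config_.mandatory_ga_weeks) | (bw < self.config_.mandatory_bw_g)
        prob = predict_probability(self.model_, igf1, sepsis)
        tiers = np.where(
            mandatory, "mandatory",
            np.where(prob > self.config_.probability_cutoff, "high_risk", "low_risk"),
        )
        return tiers


def parse_ga_weeks(text: str) -> float:
    """Parse gestational age given as decimal weeks or as ``W+D`` weeks+days."""
    text = str(text).strip()
    if "+" in text:
        w, d = text.split("+", 1)
        weeks, days = float(w), float(d)
        if days < 0 or days >= 7:
            raise ValueError(f"days component must be in [0, 7): {text!r}")
        return weeks + days / 7.0
    return float(text)
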