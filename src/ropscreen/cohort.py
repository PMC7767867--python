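"""Cohort domain types and delimited-text I/O.

A cohort is one row per pre-term infant: anthropometrics at birth, serum IGF1
at weeks 3 and 5 of life, a sepsis-by-week-3 flag, and the observed ROP grade.
Units are fixed: decimal weeks (gestational age), grams, centimetres, ng/ml.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .risk import LogisticRiskModel

ROP_GRADES = ("none", "non_proliferative", "proliferative")

COHORT_COLUMNS = [
    "infant_id",
    "ga_weeks",
    "birth_weight_g",
    "length_cm",
    "head_circ_cm",
    "igf1_w3",
    "igf1_w5",
    "sepsis_w3",
    "rop_grade",
]

_OPTIONAL_COLUMNS = {"length_cm", "head_circ_cm", "igf1_w5"}


class InfantRecord(BaseModel):
    """One pre-term infant."""

    model_config = ConfigDict(frozen=True)

    infant_id: str
    ga_weeks: float = Field(gt=0, description="gestational age at birth, decimal weeks")
    birth_weight_g: float = Field(gt=0)
    length_cm: Optional[float] = Field(default=None, gt=0)
    head_circ_cm: Optional[float] = Field(default=None, gt=0)
    igf1_w3: float = Field(gt=0, description="serum IGF1 at week 3, ng/ml")
    igf1_w5: Optional[float] = Field(default=None, gt=0, description="serum IGF1 at week 5, ng/ml")
    sepsis_w3: int = Field(ge=0, le=1, description="sepsis diagnosed in first 3 weeks")
    rop_grade: Literal["none", "non_proliferative", "proliferative"]


class CohortParams(BaseModel):
    """All distributional parameters governing synthetic cohort generation.

    The defaults describe the prospective validation stratum: infants of
    30-32 weeks gestation and 1,250-1,500 g, a latent high-risk subgroup of
    20.9% with depressed week-3 IGF1 (30.48 vs 51 ng/ml) and elevated sepsis
    prevalence (15.6% vs 6.6%), ROP generated from a logistic model in IGF1
    and sepsis, and grade-conditional week-3->5 IGF1 percentage increases of
    14.10 / 21.47 / 28.97% (none / non-proliferative / proliferative).
    """

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1, default=153)
    ga_range_weeks: tuple[float, float] = (30.0, 32.0)
    bw_range_g: tuple[float, float] = (1250.0, 1500.0)
    igf1_w3_mean_by_risk: tuple[float, float] = (51.0, 30.48)  # (low-risk, high-risk)
    igf1_w3_sd: float = Field(gt=0, default=5.0)
    sepsis_rate_by_risk: tuple[float, float] = (0.066, 0.156)
    high_risk_frac: float = Field(ge=0, le=1, default=0.209)
    rop_model: LogisticRiskModel = LogisticRiskModel(
        intercept=3.48, beta_igf1=-0.19, beta_sepsis=0.8
    )
    p_proliferative: float = Field(ge=0, le=1, default=0.2)
    pct_increase_mean_by_grade: tuple[float, float, float] = (14.10, 21.47, 28.97)
    pct_increase_sd: float = Field(ge=0, default=20.0)
    ga_bw_coupling: float = Field(ge=0, le=1, default=0.3)
    missing_w5_rate: float = Field(ge=0, le=1, default=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self):
        for name in ("ga_range_weeks", "bw_range_g"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: range must satisfy min < max")
        for name in ("sepsis_rate_by_risk",):
            if not all(0.0 <= r <= 1.0 for r in getattr(self, name)):
                raise ValueError(f"{name}: rates must lie in [0, 1]")
        if any(m <= 0 for m in self.igf1_w3_mean_by_risk):
            raise ValueError("igf1_w3_mean_by_risk: means must be > 0")
        return self


@dataclass
class Cohort:
    """Ordered collection of infants, backed by a DataFrame for vector ops."""

    frame: pd.DataFrame
    params: CohortParams | None = None

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[InfantRecord]:
        recs = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            for k in _OPTIONAL_COLUMNS:
                if pd.isna(d.get(k)):
                    d[k] = None
            recs.append(InfantRecord(**d))
        return recs

    @classmethod
    def from_records(cls, records: Iterable[InfantRecord],
                     params: CohortParams | None = None) -> "Cohort":
        rows = [r.model_dump() for r in records]
        frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
        return cls(frame=frame, params=params)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort is missing mandatory columns: {missing}")
    unknown = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise ValueError(f"cohort has unknown columns: {unknown}")
    frame = frame[COHORT_COLUMNS].copy()
    frame["infant_id"] = frame["infant_id"].astype(str)
    for col in ("ga_weeks", "birth_weight_g", "length_cm", "head_circ_cm",
                "igf1_w3", "igf1_w5"):
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    frame["sepsis_w3"] = frame["sepsis_w3"].astype(int)

    if frame["infant_id"].duplicated().any():
        dups = frame.loc[frame["infant_id"].duplicated(), "infant_id"].tolist()
        raise ValueError(f"duplicate infant_ids: {dups[:5]}")
    _require_positive(frame, "ga_weeks")
    _require_positive(frame, "birth_weight_g")
    _require_positive(frame, "igf1_w3")
    _require_positive(frame, "igf1_w5", allow_missing=True)
    _require_positive(frame, "length_cm", allow_missing=True)
    _require_positive(frame, "head_circ_cm", allow_missing=True)
    if not frame["sepsis_w3"].isin((0, 1)).all():
        raise ValueError("sepsis_w3 must be 0/1")
    bad = ~frame["rop_grade"].isin(ROP_GRADES)
    if bad.any():
        rows = frame.index[bad].tolist()
        raise ValueError(f"invalid rop_grade at rows {rows[:5]}")
    return frame


def _require_positive(frame: pd.DataFrame, col: str, allow_missing: bool = False):
    vals = frame[col]
    bad = vals <= 0
    if not allow_missing:
        bad = bad | vals.isna()
    else:
        bad = bad & vals.notna()
    if bad.any():
        rows = frame.index[bad].tolist()
        raise ValueError(f"{col} must be > 0; violated at rows {rows[:5]}")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV, booleans as 0/1, missing values empty.

    Floats are written with shortest round-trip repr so read(write(c))
    reproduces every field to full precision.
    """
    frame = cohort.frame.copy()
    frame.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            dtype={"infant_id": str, "rop_grade": str},
            keep_default_na=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cohort file {path} is empty (no header)") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc
    if frame.empty and list(frame.columns) != COHORT_COLUMNS:
        raise ValueError(f"cohort file {path} has wrong header: {list(frame.columns)}")
    try:
        return Cohort(frame=frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
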