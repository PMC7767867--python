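"""Diagnostic-accuracy statistics for the high-risk/low-risk classification.

Builds the 2x2 screening-vs-outcome table (mandatory-tier infants are excluded
— the validation concerns only infants above both mandatory thresholds) and
computes sensitivity, specificity, PPV and NPV with Clopper-Pearson exact 95%
confidence intervals, plus the screened / excluded fractions.  Display
rounding is half-up to one decimal in percent, matching the convention under
which 3/32 prints as 9.4%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Iterable, Mapping

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable2x2",
    "MetricEstimate",
    "DiagnosticSummary",
    "build_table",
    "summarize",
    "screening_fractions",
    "round_half_up_pct",
]


def round_half_up_pct(fraction: float, decimals: int = 1) -> float:
    """Display rounding: proportion -> percent, half-up to ``decimals``."""
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return math.nan
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(repr(float(fraction))) * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """High-risk/low-risk vs ROP/no-ROP counts.

    tp: high-risk with ROP; fp: high-risk without ROP;
    fn: low-risk with ROP;  tn: low-risk without ROP.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            if iv != v or isinstance(v, bool) or iv < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, iv)
        if self.total < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_high_risk(self) -> int:
        return self.tp + self.fp

    @property
    def n_low_risk(self) -> int:
        return self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with exact 95% CI; ``defined`` is False on a zero
    denominator (the estimate is then NaN, never fabricated)."""

    value: float
    ci95: tuple[float, float]
    defined: bool = True

    @property
    def pct(self) -> float:
        return round_half_up_pct(self.value)


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    high_risk_fraction: float
    low_risk_fraction: float
    table: ContingencyTable2x2

    def to_dict(self) -> dict:
        def m(e: MetricEstimate) -> dict:
            return {
                "proportion": e.value,
                "pct": e.pct,
                "ci95": list(e.ci95),
                "defined": e.defined,
            }

        return {
            "counts": {"tp": self.table.tp, "fp": self.table.fp,
                       "fn": self.table.fn, "tn": self.table.tn},
            "sensitivity": m(self.sensitivity),
            "specificity": m(self.specificity),
            "ppv": m(self.ppv),
            "npv": m(self.npv),
            "high_risk_fraction": self.high_risk_fraction,
            "high_risk_pct": round_half_up_pct(self.high_risk_fraction),
            "low_risk_fraction": self.low_risk_fraction,
            "low_risk_pct": round_half_up_pct(self.low_risk_fraction),
        }

    def to_text(self) -> str:
        def fmt(name, e: MetricEstimate):
            if not e.defined:
                return f"{name:<12} undefined (zero denominator)"
            lo, hi = e.ci95
            return (f"{name:<12} {e.pct:6.1f}%   "
                    f"[95% CI {round_half_up_pct(lo):5.1f}-{round_half_up_pct(hi):5.1f}%]")

        t = self.table
        lines = [
            "2x2 validation table (mandatory tier excluded)",
            f"  high-risk: ROP {t.tp:4d}   no ROP {t.fp:4d}",
            f"  low-risk : ROP {t.fn:4d}   no ROP {t.tn:4d}",
            fmt("Sensitivity", self.sensitivity),
            fmt("Specificity", self.specificity),
            fmt("PPV", self.ppv),
            fmt("NPV", self.npv),
            f"{'High-risk':<12} {round_half_up_pct(self.high_risk_fraction):6.1f}% of cohort",
            f"{'Low-risk':<12} {round_half_up_pct(self.low_risk_fraction):6.1f}% of cohort",
        ]
        return "\n".join(lines)


def build_table(decisions: Iterable, outcomes: Mapping[str, str]) -> ContingencyTable2x2:
    """Cross high-risk/low-risk decisions with observed ROP.

    ``decisions`` yields objects with ``infant_id`` and ``tier``;
    ``outcomes`` maps infant_id to the ROP grade (ROP positive iff the grade
    differs from ``"none"``).  Mandatory-tier infants are excluded; ids
    present on one side only raise a keyed error.
    """
    tp = fp = fn = tn = 0
    missing = []
    seen = set()
    for d in decisions:
        seen.add(d.infant_id)
        if d.tier == "mandatory":
            continue
        if d.infant_id not in outcomes:
            missing.append(d.infant_id)
            continue
        rop = outcomes[d.infant_id] != "none"
        if d.tier == "high_risk":
            tp, fp = tp + rop, fp + (not rop)
        elif d.tier == "low_risk":
            fn, tn = fn + rop, tn + (not rop)
        else:
            raise ValueError(f"unknown tier {d.tier!r} for {d.infant_id}")
    if missing:
        raise KeyError(f"no outcome for infant_ids: {sorted(missing)[:10]}")
    extra = sorted(set(outcomes) - seen)
    if extra:
        raise KeyError(f"outcomes given for unknown infant_ids: {extra[:10]}")
    return ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def _estimate(k: int, n: int) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(value=math.nan, ci95=(math.nan, math.nan), defined=False)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return MetricEstimate(value=k / n, ci95=(float(lo), float(hi)))


def summarize(table: ContingencyTable2x2) -> DiagnosticSummary:
    """All four accuracy metrics with Clopper-Pearson exact 95% CIs."""
    hi_frac, lo_frac = screening_fractions(table.total, table.n_high_risk)
    return DiagnosticSummary(
        sensitivity=_estimate(table.tp, table.tp + table.fn),
        specificity=_estimate(table.tn, table.tn + table.fp),
        ppv=_estimate(table.tp, table.tp + table.fp),
        npv=_estimate(table.tn, table.tn + table.fn),
        high_risk_fraction=hi_frac,
        low_risk_fraction=lo_frac,
        table=table,
    )


def screening_fractions(n_total: int, n_high_risk: int) -> tuple[float, float]:
    """Fractions of the validation cohort triaged high / low risk.

    Computed in rational arithmetic so the two fractions are exactly
    complementary before any display rounding.
    """
    if n_total < 1 or not (0 <= n_high_risk <= n_total):
        raise ValueError(f"invalid counts: n_total={n_total}, n_high_risk={n_high_risk}")
    hi = Fraction(n_high_risk, n_total)
    lo = 1 - hi
    return float(hi), float(lo)
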