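"""Week-3 -> week-5 IGF1 trajectory statistics and group-comparison tests.

The trajectory statistic is the percentage increase in serum IGF1 between
weeks 3 and 5 of life relative to the week-3 level; its mean rises with ROP
grade (larger surges accompany proliferative disease).  Group comparisons use
Student's/Welch's t or Mann-Whitney U for quantitative variables (chosen by a
Shapiro-Wilk normality gate in ``auto`` mode), Pearson's chi-square for
categorical ones, and one-way ANOVA across the three grades.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, ROP_GRADES

__all__ = [
    "TrajectorySummary",
    "TestResult",
    "pct_increase",
    "summarize_by_grade",
    "compare_groups",
    "chi_square_2xk",
    "anova_oneway",
]

# exact Mann-Whitney is used below this per-group size; beyond it the normal
# approximation with tie and continuity corrections takes over
_EXACT_MAX_MIN_N = 8
_EXACT_MAX_COMBOS = 500_000


def pct_increase(igf1_w3: float, igf1_w5: float) -> float:
    """100 * (week5 - week3) / week3; negative when levels fall."""
    w3 = float(igf1_w3)
    w5 = float(igf1_w5)
    if not (math.isfinite(w3) and math.isfinite(w5)) or w3 <= 0 or w5 <= 0:
        raise ValueError("both IGF1 measurements must be finite and > 0")
    return 100.0 * (w5 - w3) / w3


@dataclass(frozen=True)
class TrajectorySummary:
    """Per-grade summary of the percentage-increase statistic."""

    grade: str
    n: int
    mean_pct_increase: float
    ci95: tuple[float, float]
    quartiles: tuple[float, float, float]  # (q1, median, q3)
    n_missing: int = 0
    available: bool = True

    @classmethod
    def unavailable(cls, grade: str, n: int, n_missing: int) -> "TrajectorySummary":
        nan = math.nan
        return cls(grade=grade, n=n, mean_pct_increase=nan, ci95=(nan, nan),
                   quartiles=(nan, nan, nan), n_missing=n_missing, available=False)


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = values.size
    mean = float(np.mean(values))
    if n < 2:
        return (mean, mean)
    sem = float(np.std(values, ddof=1)) / math.sqrt(n)
    tq = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1))
    return (mean - tq * sem, mean + tq * sem)


def summarize_by_grade(cohort: Cohort) -> dict[str, TrajectorySummary]:
    """Mean, symmetric t-based 95% CI and quartiles of the percentage
    increase, per ROP grade.

    Infants lacking a week-5 measurement are excluded and counted in
    ``n_missing``; a grade with fewer than 2 complete trajectories is marked
    unavailable rather than summarized.
    """
    frame = cohort.frame
    out: dict[str, TrajectorySummary] = {}
    for grade in ROP_GRADES:
        sub = frame[frame["rop_grade"] == grade]
        complete = sub[sub["igf1_w5"].notna()]
        n_missing = len(sub) - len(complete)
        if len(complete) < 2:
            out[grade] = TrajectorySummary.unavailable(grade, len(complete), n_missing)
            continue
        delta = (
            100.0
            * (complete["igf1_w5"] - complete["igf1_w3"])
            / complete["igf1_w3"]
        ).to_numpy()
        q1, med, q3 = np.percentile(delta, [25, 50, 75])  # linear interpolation
        out[grade] = TrajectorySummary(
            grade=grade,
            n=int(delta.size),
            mean_pct_increase=float(np.mean(delta)),
            ci95=_t_ci(delta),
            quartiles=(float(q1), float(med), float(q3)),
            n_missing=n_missing,
        )
    return out


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: Optional[float | tuple[float, float]] = None
    defined: bool = True

    def __post_init__(self):
        if self.defined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _mwu_exact_enumeration(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Handles ties via midranks; feasible only for small pooled samples.
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    le = ge = total = 0
    idx = range(n1 + n2)
    eps = 1e-9
    for comb in itertools.combinations(idx, n1):
        u = float(np.sum(ranks[list(comb)]) - n1 * (n1 + 1) / 2.0)
        le += u <= u_obs + eps
        ge += u >= u_obs - eps
        total += 1
    p = min(1.0, 2.0 * min(le / total, ge / total))
    return u_obs, p


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   mode: str = "auto") -> TestResult:
    """Two-group comparison of a quantitative variable.

    ``mode``: ``student_t`` (pooled variance), ``welch_t``, ``mann_whitney_u``,
    or ``auto`` — Shapiro-Wilk at alpha=0.05 on each group chooses Welch's t
    when both look normal, Mann-Whitney otherwise.  Mann-Whitney is exact
    (full enumeration, tie-safe) while min(n) <= 8 and the enumeration is
    tractable; the tie-free exact distribution or the tie/continuity-corrected
    normal approximation is used beyond that.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if mode not in ("auto", "student_t", "welch_t", "mann_whitney_u"):
        raise ValueError(f"unknown mode {mode!r}")
    min_n = 2 if mode != "mann_whitney_u" else 1
    if a.size < min_n or b.size < min_n:
        raise ValueError("groups too small for the requested test")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(test_name=mode if mode != "auto" else "mann_whitney_u",
                          statistic=math.nan, p_value=math.nan, defined=False)

    if mode == "auto":
        normal = all(
            g.size >= 3 and np.ptp(g) > 0 and stats.shapiro(g).pvalue > 0.05
            for g in (a, b)
        )
        mode = "welch_t" if normal else "mann_whitney_u"

    if mode in ("student_t", "welch_t"):
        equal_var = mode == "student_t"
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        df = float(res.df)
        return TestResult(test_name=mode, statistic=float(res.statistic),
                          p_value=float(res.pvalue), df=df)

    # Mann-Whitney U
    n1, n2 = a.size, b.size
    if min(n1, n2) <= _EXACT_MAX_MIN_N:
        ties = np.unique(pooled).size < pooled.size
        if not ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return TestResult(test_name="mann_whitney_u",
                              statistic=float(res.statistic),
                              p_value=float(res.pvalue))
        if math.comb(n1 + n2, n1) <= _EXACT_MAX_COMBOS:
            u, p = _mwu_exact_enumeration(a, b)
            return TestResult(test_name="mann_whitney_u", statistic=u, p_value=p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return TestResult(test_name="mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(res.pvalue))


def chi_square_2xk(table: Sequence[Sequence[float]], yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("table must be 2-dimensional and non-empty")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("all row and column sums must be positive")
    res = stats.chi2_contingency(arr, correction=yates)
    return TestResult(test_name="chi_square", statistic=float(res.statistic),
                      p_value=float(res.pvalue), df=float(res.dof))


def anova_oneway(*groups: Sequence[float]) -> TestResult:
    """One-way ANOVA F-test across k >= 2 groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    pooled = np.concatenate(gs)
    k = len(gs)
    df = (float(k - 1), float(pooled.size - k))
    if np.ptp(pooled) == 0:
        # no variance anywhere: no evidence against equal means
        return TestResult(test_name="anova_f", statistic=0.0, p_value=1.0, df=df)
    res = stats.f_oneway(*gs)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(stat):  # within-group variance zero but means differ
        return TestResult(test_name="anova_f", statistic=math.inf, p_value=0.0, df=df)
    return TestResult(test_name="anova_f", statistic=stat, p_value=p, df=df)
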