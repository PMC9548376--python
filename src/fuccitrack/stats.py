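"""Genotype comparison statistics for phase-duration tables.

Mann-Whitney U with exact small-sample enumeration or a tie-corrected
normal approximation, Bonferroni adjustment, the boxplot summary convention
(quartiles, 1.5*IQR whiskers), a Welch t utility, and a Kaplan-Meier median
for right-censored duration tables.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "UStatResult",
    "BoxplotSummary",
    "ComparisonReport",
    "mann_whitney",
    "bonferroni",
    "summarize_distribution",
    "compare_cohorts",
    "welch_t",
    "km_median",
    "phase_km_median",
]

log = logging.getLogger(__name__)

EXACT_MAX_N = 8


@dataclass(frozen=True)
class UStatResult:
    u: float
    n1: int
    n2: int
    p: float
    method: str  # "exact_enumeration" | "normal_tie_corrected"


@dataclass(frozen=True)
class BoxplotSummary:
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n_outliers: int


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x against y using midranks (ties count 1/2)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> UStatResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of rank assignments when both samples have
    at most 8 observations and there are no ties; otherwise a normal
    approximation with midranks, tie correction and continuity correction.
    ``u`` is reported for sample ``x``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not has_ties:
        # distribution of U over all C(n1+n2, n1) equally likely assignments
        n = n1 + n2
        counts: dict[int, int] = {}
        base = n1 * (n1 + 1) // 2
        for comb in combinations(range(1, n + 1), n1):
            ui = sum(comb) - base
            counts[ui] = counts.get(ui, 0) + 1
        total = math.comb(n, n1)
        u_int = int(round(u))
        lo = min(u_int, n1 * n2 - u_int)
        p = 2 * sum(c for ui, c in counts.items() if ui <= lo) / total
        return UStatResult(u, n1, n2, min(1.0, p), "exact_enumeration")

    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return UStatResult(u, n1, n2, 1.0, "normal_tie_corrected")
    num = u - mu
    cc = 0.5 * np.sign(num)
    z = (num - cc) / math.sqrt(var) if num != 0 else 0.0
    p = min(1.0, 2 * sps.norm.sf(abs(z)))
    return UStatResult(u, n1, n2, p, "normal_tie_corrected")


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be >= number of p-values")
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-value {p} outside (0, 1]")
    return [min(1.0, m * p) for p in p_values]


def summarize_distribution(values: Sequence[float]) -> BoxplotSummary:
    """Quartiles (linear interpolation) and 1.5*IQR whiskers."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_lo = float(inside.min())
    whisker_hi = float(inside.max())
    n_out = int(((v < whisker_lo) | (v > whisker_hi)).sum())
    return BoxplotSummary(len(v), float(med), float(q1), float(q3),
                          whisker_lo, whisker_hi, n_out)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Two-sample unequal-variance t test; returns (t, p)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                        equal_var=False)
    return float(res.statistic), float(res.pvalue)


def km_median(durations: Sequence[float], observed: Sequence[bool]) -> float:
    """Kaplan-Meier median of right-censored durations.

    ``observed[i]`` is True for a complete duration and False for a
    censored span (event not yet seen when observation stopped).  Returns
    the smallest time at which the product-limit survival estimate drops
    to <= 0.5, or NaN if it never does.
    """
    t = np.asarray(list(durations), dtype=float)
    e = np.asarray(list(observed), dtype=bool)
    if t.size == 0:
        raise ValueError("empty duration table")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    s = 1.0
    n_at_risk = len(t)
    i = 0
    while i < len(t):
        j = i
        d = 0
        while j < len(t) and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d:
            s *= 1 - d / n_at_risk
            if s <= 0.5:
                return float(t[i])
        n_at_risk -= j - i
        i = j
    return float("nan")


def phase_km_median(durations: pd.DataFrame, audit: pd.DataFrame,
                    phase: str) -> float:
    """Censoring-aware median of one phase from a pipeline duration table.

    Complete durations count as events; end-censored audit spans (birth
    observed, bounding event not reached before the movie ended) enter as
    right-censored.  Start-censored spans have an unobserved birth and are
    excluded.
    """
    complete = durations.loc[durations["phase"] == phase, "duration_min"]
    right = audit.loc[(audit["phase"] == phase)
                      & (audit["censor_type"] == "end"), "duration_min"]
    return km_median(
        list(complete) + list(right),
        [True] * len(complete) + [False] * len(right))


@dataclass
class PhaseComparison:
    phase: str
    summary_a: BoxplotSummary
    summary_b: BoxplotSummary
    line_a: str
    line_b: str
    test: UStatResult
    p_adjusted: float


@dataclass
class ComparisonReport:
    label_a: str
    label_b: str
    m_tests: int
    phases: dict  # phase -> PhaseComparison

    def to_dict(self) -> dict:
        out = {"group_a": self.label_a, "group_b": self.label_b,
               "m_tests": self.m_tests, "phases": {}}
        for name, pc in self.phases.items():
            out["phases"][name] = {
                "n_a": pc.summary_a.n, "n_b": pc.summary_b.n,
                "median_a": pc.summary_a.median, "median_b": pc.summary_b.median,
                "summary_a": pc.line_a, "summary_b": pc.line_b,
                "U": pc.test.u, "p": pc.test.p, "p_adjusted": pc.p_adjusted,
                "method": pc.test.method,
            }
        return out

    def to_text(self) -> str:
        lines = [f"{self.label_a} vs {self.label_b} "
                 f"(Bonferroni m={self.m_tests})"]
        for name, pc in self.phases.items():
            lines.append(f"  {name}: {self.label_a} {pc.line_a} (n={pc.summary_a.n}) | "
                         f"{self.label_b} {pc.line_b} (n={pc.summary_b.n}) | "
                         f"U={pc.test.u:.1f}, p={pc.test.p:.3g}, "
                         f"adj p={pc.p_adjusted:.3g}")
        return "\n".join(lines)


def _median_sd_line(values: np.ndarray) -> str:
    return f"{np.median(values):.0f}±{np.std(values, ddof=1):.0f} min" \
        if values.size > 1 else f"{np.median(values):.0f} min"


def compare_cohorts(durations_a: pd.DataFrame, durations_b: pd.DataFrame,
                    phases: Sequence[str] = ("G1", "SG2M"),
                    m_tests: int = 2,
                    label_a: str = "wt", label_b: str = "mut") -> ComparisonReport:
    """Per-phase two-cohort comparison of duration tables.

    Input frames follow the duration-table schema (``phase``,
    ``duration_min`` columns).  Phases absent from either cohort are
    skipped with a warning.  Reported p-values are Bonferroni-adjusted
    over ``m_tests``.
    """
    report = ComparisonReport(label_a, label_b, m_tests, {})
    for phase in phases:
        va = durations_a.loc[durations_a["phase"] == phase, "duration_min"].to_numpy()
        vb = durations_b.loc[durations_b["phase"] == phase, "duration_min"].to_numpy()
        if va.size == 0 or vb.size == 0:
            log.warning("phase %s missing in one cohort; skipped", phase)
            continue
        test = mann_whitney(va, vb)
        p_adj = bonferroni([test.p], m_tests)[0]
        report.phases[phase] = PhaseComparison(
            phase, summarize_distribution(va), summarize_distribution(vb),
            _median_sd_line(va), _median_sd_line(vb), test, p_adj)
    return report
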