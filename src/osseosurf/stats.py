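"""Nonparametric statistical layer of the accuracy study.

Descriptives are reported as median and interquartile range.  Group
comparisons use the Wilcoxon signed-rank test (paired), Kruskal–Wallis
(k groups) followed by pairwise Mann–Whitney U with Bonferroni
adjustment, and Shapiro–Wilk normality screening.  All p-values are
two-sided.

Small samples get *exact* p-values by full enumeration (all 2^n sign
patterns for Wilcoxon, all C(n, n_a) group labelings for Mann–Whitney);
above n = 12 a normal approximation with tie correction takes over.
The switchover is recorded in each result's ``method`` field.
Normality screening is reported but never gates the pipeline: the
nonparametric path always runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats as _sps

__all__ = [
    "StatSummary",
    "StatResult",
    "describe",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "kruskal_wallis",
    "bonferroni",
    "shapiro_wilk",
]

#: largest total sample size for which exact enumeration is used
EXACT_N_MAX = 12


@dataclass(frozen=True)
class StatSummary:
    median: float
    iqr: float

    def __post_init__(self) -> None:
        if self.iqr < 0:
            raise ValueError("IQR cannot be negative")


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    p_adjusted: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "n": list(self.n),
            "method": self.method,
            "notes": self.notes,
        }


def describe(values) -> StatSummary:
    """Median and IQR (Q3 − Q1, linear-interpolation quantile rule)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot describe an empty sample")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # default 'linear' interpolation
    return StatSummary(median=float(np.median(v)), iqr=float(q3 - q1))


# ----------------------------------------------------------------------
# Wilcoxon signed rank
# ----------------------------------------------------------------------

def wilcoxon_signed_rank(paired_differences) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original rule) and the
    dropped count recorded.  Exact p by enumerating all sign patterns
    for n ≤ 12 (correct under ties, which receive average ranks);
    normal approximation with tie correction above.
    """
    d = np.asarray(paired_differences, dtype=float)
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: test degenerate")
    if n < 3:
        raise ValueError(f"need at least 3 nonzero differences, got {n}")
    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0

    if n <= EXACT_N_MAX:
        signs = np.array(list(product((0.0, 1.0), repeat=n)))
        w_all = signs @ ranks
        dev = abs(w_plus - mu)
        p = float(np.mean(np.abs(w_all - mu) >= dev - 1e-12))
        method = "exact-enumeration"
    else:
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if sigma2 <= 0:
            raise ValueError("degenerate variance in Wilcoxon approximation")
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(2.0 * _sps.norm.sf(abs(z)))
        method = "normal-approx-tie-corrected"
    notes = f"{n_zero} zero differences dropped" if n_zero else ""
    return StatResult("wilcoxon-signed-rank", w_plus, min(p, 1.0), (n,), method, notes=notes)


# ----------------------------------------------------------------------
# Mann–Whitney U
# ----------------------------------------------------------------------

def _u_statistic(pooled_ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(np.sum(pooled_ranks[list(idx_a)]) - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b) -> StatResult:
    """Two-sided two-sample Mann–Whitney U test.

    Exact p by enumerating all group labelings of the pooled sample for
    n_a + n_b ≤ 12 (tie-safe); normal approximation with tie correction
    otherwise.  The classical two-sample test is used (not the pooled
    Kruskal–Wallis-rank variant some packages report for pairwise
    follow-ups); the method label records this.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    mu = n_a * n_b / 2.0

    if n_a + n_b <= EXACT_N_MAX:
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks, idx, n_a)
            hits += abs(u - mu) >= dev - 1e-12
            total += 1
        p = hits / total
        method = "exact-enumeration"
    else:
        n = n_a + n_b
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            raise ValueError("degenerate variance: all pooled values identical")
        z = (u_obs - mu) / np.sqrt(sigma2)
        p = float(2.0 * _sps.norm.sf(abs(z)))
        method = "normal-approx-tie-corrected"
    return StatResult(
        "mann-whitney-u", u_obs, min(p, 1.0), (n_a, n_b), method,
        notes="classical two-sample U",
    )


# ----------------------------------------------------------------------
# Kruskal–Wallis
# ----------------------------------------------------------------------

def kruskal_wallis(groups) -> StatResult:
    """Kruskal–Wallis H test with tie correction, chi-squared p (k−1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = _sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    notes = ""
    if correction <= 0:
        h = 0.0  # all observations identical
        p = 1.0
        notes = "degenerate: all observations identical"
    else:
        h /= correction
        p = float(_sps.chi2.sf(h, df=len(groups) - 1))
    return StatResult(
        "kruskal-wallis", float(h), p, tuple(len(g) for g in groups),
        "chi2-tie-corrected", notes=notes,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p) per value; m defaults to len."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m ({m}) must be at least the number of p-values ({p.size})")
    return np.minimum(1.0, m * p)


def shapiro_wilk(values) -> StatResult:
    """Shapiro–Wilk normality screen (3 ≤ n ≤ 5000)."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality test degenerate")
    w, p = _sps.shapiro(v)
    return StatResult("shapiro-wilk", float(w), float(p), (v.size,), "reference")
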