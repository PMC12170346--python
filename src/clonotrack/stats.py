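"""Statistical primitives shared by all pipeline stages.

Exact and asymptotic contingency-table tests, two-sample location tests and
Benjamini-Hochberg multiplicity correction.  Everything downstream (clonal
sharing tests, phenotype-transition tests, differential expression) funnels
through these functions so that test conventions are defined in one place.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi2_independence",
    "fisher_exact_rxc",
    "student_t_two_sided_p",
    "two_sample_t_test",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
]


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("table must be at least 2 x 2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if counts.sum() < 1:
            raise ValueError("grand total must be at least 1")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(counts.shape[1])]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class TestResult:
    """Statistic, degrees of freedom and two-sided p-value of one test."""

    statistic: float
    df: float
    p: float

    def __post_init__(self) -> None:
        # p is clamped into (0, 1]; a p of exactly zero is a numerical
        # artefact of the upper-tail evaluation, not a real probability.
        self.p = float(min(max(self.p, 5e-324), 1.0))
        if self.df < 0:
            raise ValueError("df must be non-negative")


def chi2_independence(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction.

    X^2 = sum (O - E)^2 / E with df = (r-1)(c-1); the p-value is the upper
    tail of the chi-squared distribution.  Raises if any row or column
    margin is zero (expected counts would be undefined).
    """
    counts = table.counts
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    for name, margins, labels in (
        ("row", row_m, table.row_labels),
        ("column", col_m, table.col_labels),
    ):
        zero = np.where(margins == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero {name} margin for {name} {labels[zero[0]]!r}; "
                "drop empty rows/columns before testing"
            )
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    result = TestResult(statistic=float(stat), df=float(df), p=float(p))
    logger.info("chi2_independence: X2=%.4f df=%g p=%.4g", result.statistic, result.df, result.p)
    return result


def _enumerate_table_log_probs(
    row_margins: np.ndarray, col_margins: np.ndarray
) -> np.ndarray:
    """Log probability of every non-negative integer table with the given
    margins under the multiple hypergeometric (fixed-margins) distribution.

    Depth-first enumeration filling the table row by row; the last cell of
    each row and the whole last row are forced by the margins.
    """
    r, c = len(row_margins), len(col_margins)
    n = int(row_margins.sum())
    lgam = math.lgamma
    log_const = (
        sum(lgam(m + 1) for m in row_margins)
        + sum(lgam(m + 1) for m in col_margins)
        - lgam(n + 1)
    )
    out: list[float] = []
    cells_log = [0.0] * (r * c)

    def fill(i: int, j: int, rem_row: int, rem_cols: np.ndarray, acc: float) -> None:
        if i == r - 1:
            # last row forced by the column margins
            total = acc
            for jj in range(c):
                total -= lgam(rem_cols[jj] + 1)
            out.append(log_const + total)
            return
        if j == c - 1:
            v = rem_row
            if v > rem_cols[j]:
                return
            rem_cols[j] -= v
            fill(i + 1, 0, int(row_margins[i + 1]), rem_cols, acc - lgam(v + 1))
            rem_cols[j] += v
            return
        hi = min(rem_row, int(rem_cols[j]))
        for v in range(hi + 1):
            rem_cols[j] -= v
            fill(i, j + 1, rem_row - v, rem_cols, acc - lgam(v + 1))
            rem_cols[j] += v

    fill(0, 0, int(row_margins[0]), col_margins.copy(), 0.0)
    return np.array(out)


def fisher_exact_rxc(
    table: ContingencyTable, max_total: int = 500, rel_tol: float = 1e-9
) -> float:
    """Exact conditional (Fisher) test for an r x c table.

    Enumerates every table with the observed margins; a table's probability
    is (prod row! * prod col!) / (N! * prod cell!).  The two-sided p-value
    sums the probabilities of all tables whose probability does not exceed
    the observed one (probability-mass ordering), with a relative tie
    tolerance ``rel_tol``.  In the 2x2 case this coincides with the
    hypergeometric two-sided test.
    """
    counts = table.counts
    n = int(counts.sum())
    if n > max_total:
        raise ValueError(
            f"grand total {n} exceeds the enumeration guard ({max_total}); "
            "an exact enumeration would be intractable - use a Monte Carlo "
            "approximation instead (not implemented here)"
        )
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    # all-zero rows/columns carry no information; drop them
    counts = counts[row_m > 0][:, col_m > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)

    lgam = math.lgamma
    log_obs = (
        sum(lgam(m + 1) for m in row_m)
        + sum(lgam(m + 1) for m in col_m)
        - lgam(n + 1)
        - sum(lgam(v + 1) for v in counts.ravel())
    )
    log_probs = _enumerate_table_log_probs(row_m, col_m)
    probs = np.exp(log_probs)
    total = probs.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-7):
        raise AssertionError(f"enumerated probabilities sum to {total}, not 1")
    p_obs = math.exp(log_obs)
    p = float(probs[probs <= p_obs * (1.0 + rel_tol)].sum())
    p = min(p, 1.0)
    logger.info("fisher_exact_rxc: shape=%s N=%d p=%.4g", counts.shape, n, p)
    return p


def student_t_two_sided_p(t: float, df: float) -> float:
    """Two-sided p-value P(|T_df| >= |t|) of a Student t statistic."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(2.0 * sps.t.sf(abs(t), df))


def two_sample_t_test(
    x: Sequence[float], y: Sequence[float], pooled: bool = True
) -> TestResult:
    """Two-sided independent two-sample t-test (Student or Welch).

    With ``pooled=True`` the classic Student test with pooled variance and
    df = n_x + n_y - 2 is used, otherwise Welch's test with Satterthwaite
    df.  Degenerate input (both variances zero): equal means return
    statistic 0 / p 1, unequal means raise, so that NaNs never propagate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, df=float(nx + ny - 2), p=1.0)
        raise ValueError(
            "both samples have zero variance with unequal means; "
            "the t statistic is undefined (infinite)"
        )
    if pooled:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        a, b = vx / nx, vy / ny
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
    t = (x.mean() - y.mean()) / se
    result = TestResult(statistic=float(t), df=float(df), p=student_t_two_sided_p(t, df))
    logger.info("two_sample_t_test: t=%.4f df=%.2f p=%.4g", result.statistic, result.df, result.p)
    return result


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    idx = range(len(pooled))
    mean = nx * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in combinations(idx, nx):
        total += 1
        s = ranks[list(comb)].sum()
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    ``mode='exact'`` enumerates all assignments (requires no ties and
    combined n <= 12 under 'auto'); ``mode='normal'`` uses the normal
    approximation with tie and continuity corrections.  The reported
    statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(pooled) <= 12 and not has_ties) else "normal"
    ranks = sps.rankdata(pooled)
    rank_sum = float(ranks[: len(x)].sum())
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        p = _rank_sum_exact_p(x, y)
    elif mode == "normal":
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    result = TestResult(statistic=rank_sum, df=0.0, p=p)
    logger.info("wilcoxon_rank_sum: R=%.1f mode=%s p=%.4g", rank_sum, mode, result.p)
    return result


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j>=i} m * p_(j) / j on the sorted p-values, mapped back to
    the input order and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
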