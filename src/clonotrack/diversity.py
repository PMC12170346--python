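"""Clonal-expansion summaries: size bins, Shannon entropy and D50.

All operations take a vector of clonotype sizes (number of member cells per
clonotype) for one sample, arm or compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContingencyTable, TestResult, chi2_independence

SIZE_BINS = ("1", "2-5", "6-10", "11-20", "21+")
_BIN_EDGES = (1, 2, 6, 11, 21)  # lower edge of each bin


@dataclass
class DiversityProfile:
    """Shannon entropy (bits, and normalized to [0, 1]) and D50 of a repertoire."""

    shannon_bits: float
    shannon_normalized: float
    d50_count: int
    d50_percent: float
    n_clonotypes: int
    n_cells: int


@dataclass
class SizeBinDistribution:
    """Clonotype sizes binned as 1 / 2-5 / 6-10 / 11-20 / 21+."""

    counts: np.ndarray  # raw counts per bin (clonotypes or cells)
    basis: str  # "clonotypes" or "cells"

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(SIZE_BINS), name=self.basis)


def _check_sizes(sizes) -> np.ndarray:
    sizes = np.asarray(sizes)
    if sizes.size == 0:
        raise ValueError("empty size vector")
    if np.any(sizes <= 0):
        raise ValueError("clonotype sizes must be positive")
    return sizes.astype(np.int64)


def shannon_entropy(sizes) -> float:
    """Shannon entropy (base 2) of the clonotype frequency distribution."""
    sizes = _check_sizes(sizes)
    p = sizes / sizes.sum()
    return float(-(p * np.log2(p)).sum())


def normalized_shannon_entropy(sizes) -> float:
    """Shannon entropy divided by log2 of the clonotype count (0 for one clonotype)."""
    sizes = _check_sizes(sizes)
    if sizes.size == 1:
        return 0.0
    return shannon_entropy(sizes) / float(np.log2(sizes.size))


def d50(sizes) -> tuple[int, float]:
    """Minimal number of top clonotypes covering >= 50% of cells.

    Returns (count, percent-of-clonotypes).  Sizes are sorted descending
    with a stable sort; the >= 50% convention means a single clone holding
    exactly half the cells gives count 1.
    """
    sizes = _check_sizes(sizes)
    ordered = np.sort(sizes, kind="stable")[::-1]
    target = sizes.sum() / 2.0
    cum = np.cumsum(ordered)
    count = int(np.searchsorted(cum, target, side="left") + 1)
    return count, 100.0 * count / sizes.size


def diversity_profile(sizes) -> DiversityProfile:
    sizes = _check_sizes(sizes)
    count, percent = d50(sizes)
    return DiversityProfile(
        shannon_bits=shannon_entropy(sizes),
        shannon_normalized=normalized_shannon_entropy(sizes),
        d50_count=count,
        d50_percent=percent,
        n_clonotypes=int(sizes.size),
        n_cells=int(sizes.sum()),
    )


def bin_clonotype_sizes(sizes, basis: str = "clonotypes") -> SizeBinDistribution:
    """Histogram of clonotype sizes over the five standard bins.

    ``basis='clonotypes'`` counts each clonotype once; ``basis='cells'``
    weights each clonotype by its size.
    """
    if basis not in ("clonotypes", "cells"):
        raise ValueError(f"unknown basis {basis!r}")
    sizes = _check_sizes(sizes)
    idx = np.searchsorted(_BIN_EDGES, sizes, side="right") - 1
    weights = sizes if basis == "cells" else np.ones_like(sizes)
    counts = np.bincount(idx, weights=weights, minlength=len(SIZE_BINS)).astype(np.int64)
    return SizeBinDistribution(counts=counts, basis=basis)


def compare_size_distributions(
    dist_a: SizeBinDistribution, dist_b: SizeBinDistribution
) -> TestResult:
    """Chi-squared test of the two binned size distributions.

    Bins empty in both groups are pooled away (dropping a zero column is
    numerically identical to merging it into a neighbour) so that no
    expected count is zero.
    """
    if dist_a.basis != dist_b.basis:
        raise ValueError("distributions use different counting bases")
    a, b = dist_a.counts.astype(np.int64), dist_b.counts.astype(np.int64)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty distribution")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2:
        return TestResult(statistic=0.0, df=0.0, p=1.0)
    table = ContingencyTable(np.vstack([a, b]))
    return chi2_independence(table)
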