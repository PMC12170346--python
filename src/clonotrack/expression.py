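"""Expression-level comparison of clonally expanded vs non-expanded cells.

Cells of a phenotype subset (regulatory T cells by default) at a timepoint
are labelled expanded when their clonotype has at least ``min_size``
members within that subset and timepoint.  The module then provides
per-gene Wilcoxon differential expression with Benjamini-Hochberg
correction, a signal-to-noise-ranked gene-set enrichment analysis with
permutation-based normalization, and per-cell signature scoring.

Expression is handled as a cells x genes pandas DataFrame of
log-normalized values (log1p of depth-normalized counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu

from .clonotyping import ClonotypeAssignment
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9
MIN_CELLS_EXPRESSING = 3


@dataclass
class GseaResult:
    """Enrichment of one gene set in the ranked comparison."""

    gene_set: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list[str]


def label_expanded(
    assignment: ClonotypeAssignment,
    meta,
    subset: str = "Treg",
    timepoint: str = "post",
    min_size: int = 2,
) -> pd.Series:
    """Label subset cells as expanded / non_expanded by within-subset clonotype size.

    A cell is expanded iff its clonotype has >= min_size member cells within
    the chosen phenotype subset and timepoint.
    """
    cells = [
        m.cell_id
        for m in meta
        if m.phenotype == subset
        and m.timepoint == timepoint
        and m.cell_id in assignment.cell_to_clonotype
    ]
    if not cells:
        raise ValueError(f"no {subset} cells at timepoint {timepoint!r}")
    clono = pd.Series(
        {c: assignment.cell_to_clonotype[c] for c in cells}, name="clonotype_id"
    )
    within_sizes = clono.value_counts()
    labels = clono.map(within_sizes).ge(min_size).map(
        {True: "expanded", False: "non_expanded"}
    )
    labels.name = "expansion"
    logger.info(
        "label_expanded: %d %s cells at %s -> %d expanded, %d non-expanded",
        len(cells), subset, timepoint,
        int((labels == "expanded").sum()), int((labels == "non_expanded").sum()),
    )
    return labels


def _split_groups(expr: pd.DataFrame, labels: pd.Series):
    labels = labels.reindex(expr.index).dropna()
    groups = labels.unique()
    if set(groups) != {"expanded", "non_expanded"}:
        raise ValueError("labels must contain exactly the groups expanded/non_expanded")
    x1 = expr.loc[labels[labels == "expanded"].index]
    x2 = expr.loc[labels[labels == "non_expanded"].index]
    return x1, x2


def differential_expression(
    expr: pd.DataFrame, labels: pd.Series, min_group: int = 3
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between expanded and
    non-expanded cells, with Benjamini-Hochberg correction.

    log2FC uses the expm1-mean convention common in single-cell toolchains:
    log2((mean(expm1 x1) + eps) / (mean(expm1 x2) + eps)).  Genes expressed
    in fewer than three cells overall are excluded before testing.  A gene
    is significant when q < 0.05 and |log2FC| > 0.3.
    """
    x1, x2 = _split_groups(expr, labels)
    if len(x1) < min_group or len(x2) < min_group:
        raise ValueError(
            f"both groups need >= {min_group} cells (got {len(x1)}, {len(x2)})"
        )
    expressed = (expr > 0).sum(axis=0) >= MIN_CELLS_EXPRESSING
    dropped = int((~expressed).sum())
    if dropped:
        logger.info("excluding %d genes expressed in < %d cells", dropped, MIN_CELLS_EXPRESSING)
    genes = expr.columns[expressed]
    a = x1[genes].to_numpy()
    b = x2[genes].to_numpy()
    # vectorized two-sided Wilcoxon rank-sum with tie/continuity correction;
    # identical to stats.wilcoxon_rank_sum(mode="normal") per gene
    _, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    m1 = np.expm1(a).mean(axis=0)
    m2 = np.expm1(b).mean(axis=0)
    log2fc = np.log2((m1 + LOG2FC_EPS) / (m2 + LOG2FC_EPS))
    q = benjamini_hochberg(p)
    out = pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "p": p, "q": q,
         "significant": (q < 0.05) & (np.abs(log2fc) > 0.3)}
    )
    return out.sort_values("q", kind="stable").reset_index(drop=True)


def _signal_to_noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Broad-convention signal-to-noise ranking metric (mu1-mu2)/(s1+s2),
    with each s floored at 0.2*|mu| (0.2 when mu is 0)."""
    mus = []
    sds = []
    for x in (a, b):
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        floor = 0.2 * np.abs(mu)
        floor[mu == 0] = 0.2
        sds.append(np.maximum(sd, floor))
        mus.append(mu)
    return (mus[0] - mus[1]) / (sds[0] + sds[1])


def _enrichment_score(metric: np.ndarray, in_set: np.ndarray) -> tuple[float, int]:
    """Weighted Kolmogorov-Smirnov-style running-sum enrichment score.

    ``metric`` must be sorted descending; hit increments are |metric|^1
    normalized over the set, miss decrements 1/(N - N_hit).  Returns the
    maximum-deviation ES and the index at which it is attained.
    """
    n = metric.size
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0, 0
    w = np.abs(metric) * in_set
    denom = w.sum()
    if denom == 0:
        w = in_set.astype(float)
        denom = w.sum()
    running = np.cumsum(w / denom - (~in_set) / (n - n_hit))
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea_signal_to_noise(
    expr: pd.DataFrame,
    labels: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 5,
    phenotype_perm_min_group: int = 15,
) -> list[GseaResult]:
    """GSEA of expanded vs non-expanded cells with the signal-to-noise metric.

    Genes are ranked by (mu_exp - mu_non)/(sd_exp + sd_non); the enrichment
    score is the maximum deviation of the |metric|-weighted running sum.
    NES divides ES by the mean same-sign permutation ES; p is the same-sign
    permutation tail and q its Benjamini-Hochberg adjustment across sets.
    Phenotype (label) permutation is used when both groups have at least
    ``phenotype_perm_min_group`` cells, otherwise gene-set permutation.
    """
    rng = np.random.default_rng(seed)
    x1, x2 = _split_groups(expr, labels)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need >= 2 cells per group")
    genes = expr.columns.to_numpy()
    a, b = x1.to_numpy(), x2.to_numpy()
    metric = _signal_to_noise(a, b)
    order = np.argsort(-metric, kind="stable")
    metric_sorted = metric[order]
    genes_sorted = genes[order]
    gene_rank = {g: i for i, g in enumerate(genes_sorted)}

    usable = {}
    for name, members in gene_sets.items():
        present = [g for g in dict.fromkeys(members) if g in gene_rank]
        if len(present) >= min_set_size:
            usable[name] = present
        else:
            logger.info("gene set %s skipped (%d usable genes < %d)", name, len(present), min_set_size)

    use_phenotype_perm = min(len(x1), len(x2)) >= phenotype_perm_min_group
    stacked = np.vstack([a, b])
    n1 = len(x1)

    results: list[GseaResult] = []
    pvals = []
    for name, members in usable.items():
        in_set = np.zeros(len(genes_sorted), dtype=bool)
        idx = np.array([gene_rank[g] for g in members])
        in_set[idx] = True
        es, peak = _enrichment_score(metric_sorted, in_set)
        if es >= 0:
            leading = [g for g in genes_sorted[: peak + 1] if in_set[gene_rank[g]]]
        else:
            leading = [g for g in genes_sorted[peak:] if in_set[gene_rank[g]]]

        perm_es = np.empty(n_perm)
        if use_phenotype_perm:
            # membership follows the genes; positions follow the permuted ranking
            member_mask = np.isin(genes, members)
            for t in range(n_perm):
                perm = rng.permutation(stacked.shape[0])
                pm = _signal_to_noise(stacked[perm[:n1]], stacked[perm[n1:]])
                p_order = np.argsort(-pm, kind="stable")
                perm_es[t], _ = _enrichment_score(pm[p_order], member_mask[p_order])
        else:
            size = len(members)
            for t in range(n_perm):
                member_mask = np.zeros(len(genes_sorted), dtype=bool)
                member_mask[rng.choice(len(genes_sorted), size=size, replace=False)] = True
                perm_es[t], _ = _enrichment_score(metric_sorted, member_mask)

        same_sign = perm_es[perm_es * es > 0] if es != 0 else perm_es
        if same_sign.size == 0:
            nes = 0.0
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
        pvals.append(p)
        results.append(GseaResult(gene_set=name, es=es, nes=float(nes), p=float(p),
                                  q=np.nan, leading_edge=leading))
    if results:
        qs = benjamini_hochberg(pvals)
        for r, q in zip(results, qs):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, -abs(r.nes)))
    return results


def signature_score(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Per-cell mean of across-cell z-scored expression of the listed genes.

    Missing and zero-variance genes are excluded (logged); at least one
    usable gene is required.
    """
    present = [g for g in dict.fromkeys(genes) if g in expr.columns]
    missing = [g for g in dict.fromkeys(genes) if g not in expr.columns]
    if missing:
        logger.info("signature_score: %d listed genes absent from matrix", len(missing))
    if not present:
        raise ValueError("none of the listed genes are present in the matrix")
    sub = expr[present]
    sd = sub.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.info("signature_score: excluding %d zero-variance genes", len(constant))
        present = [g for g in present if g not in set(constant)]
        if not present:
            raise ValueError("all listed genes have zero variance")
        sub = expr[present]
        sd = sub.std(axis=0, ddof=0)
    z = (sub - sub.mean(axis=0)) / sd
    score = z.mean(axis=1)
    score.name = "signature_score"
    return score


def signature_summary(
    expr: pd.DataFrame, labels: pd.Series, genes: list[str]
) -> pd.DataFrame:
    """Per-gene group means and expanded-vs-non log2FC for heat-map export."""
    x1, x2 = _split_groups(expr, labels)
    present = [g for g in dict.fromkeys(genes) if g in expr.columns]
    if not present:
        raise ValueError("none of the listed genes are present in the matrix")
    m1 = np.expm1(x1[present]).mean(axis=0)
    m2 = np.expm1(x2[present]).mean(axis=0)
    return pd.DataFrame(
        {
            "gene": present,
            "mean_expanded": m1.to_numpy(),
            "mean_non_expanded": m2.to_numpy(),
            "log2fc": np.log2((m1 + LOG2FC_EPS) / (m2 + LOG2FC_EPS)).to_numpy(),
        }
    )


def read_expression_mtx(directory: str | Path) -> pd.DataFrame:
    """Read a MatrixMarket expression directory (matrix.mtx, genes.tsv,
    barcodes.tsv) into a cells x genes log-normalized DataFrame."""
    from scipy.io import mmread

    directory = Path(directory)
    mat = sparse.csr_matrix(mmread(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if mat.shape == (len(genes), len(cells)):
        mat = mat.T
    return pd.DataFrame(mat.toarray(), index=cells, columns=genes)


def write_expression_mtx(expr: pd.DataFrame, directory: str | Path) -> None:
    from scipy.io import mmwrite

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sparse.csr_matrix(expr.to_numpy().T))
    pd.Series(expr.columns).to_csv(directory / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(expr.index).to_csv(directory / "barcodes.tsv", sep="\t", index=False, header=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into {set name: gene list}."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 3:
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
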