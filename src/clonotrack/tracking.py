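"""Longitudinal clonotype tracking between the pre and post timepoints.

The TCR clonotype is used as a barcode relating cells across timepoints
within a patient; this never claims same-cell identity, only clonal
relatedness.  The module quantifies clonotype and cell sharing per
treatment arm, builds pre/post phenotype-transition tables (tested with
the exact r x c Fisher test), and estimates an empirical phenotype
transition matrix from all cross-timepoint cell pairs of shared
clonotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonotyping import ClonotypeAssignment
from .stats import ContingencyTable, TestResult, chi2_independence, fisher_exact_rxc

logger = logging.getLogger(__name__)

# Default collapse of phenotype labels for CD4-compartment tracking; labels
# mapping to None are excluded from transition analyses.
DEFAULT_CD4_COLLAPSE: dict[str, str | None] = {
    "Treg": "Treg",
    "CD4_naive": "naive",
    "CD4_Tcm": "Tcm",
    "CD4_Tem": "Tem",
    "CD8_naive": None,
    "CD8_Tcm": None,
    "CD8_Tem": None,
    "CD8_Temra": None,
}


@dataclass
class SharedClonotypeSet:
    """Clonotype/cell sharing between timepoints, aggregated over one arm."""

    arm: str
    shared: set[str] = field(default_factory=set)
    pre_only: set[str] = field(default_factory=set)
    post_only: set[str] = field(default_factory=set)
    n_shared_cells: int = 0
    total_cells: int = 0
    # (patient, clonotype) -> ([pre phenotypes], [post phenotypes])
    tracks: dict[tuple[str, str], tuple[list[str], list[str]]] = field(default_factory=dict)

    @property
    def n_shared_clonotypes(self) -> int:
        return len(self.shared)

    @property
    def shared_cell_fraction(self) -> float:
        return self.n_shared_cells / self.total_cells if self.total_cells else 0.0


@dataclass
class TransitionTable:
    """2 x K pre/post phenotype count table for tracked clonotypes."""

    table: ContingencyTable | None
    arm: str
    restrict_to: frozenset[str] | None
    n_tracked_clonotypes: int

    @property
    def empty(self) -> bool:
        return self.table is None


@dataclass
class TransitionMatrix:
    """Row-stochastic K x K phenotype transition matrix for one arm.

    Rows without any tracked pre-timepoint cell are undefined (NaN) and
    listed in ``undefined_rows`` rather than zero-filled.
    """

    matrix: pd.DataFrame
    counts: pd.DataFrame  # unnormalized accumulated weights
    weighting: str
    arm: str
    undefined_rows: list[str]

    @property
    def outgoing_flow(self) -> pd.Series:
        return 1.0 - pd.Series(np.diag(self.matrix), index=self.matrix.index)


def _meta_frame(meta) -> pd.DataFrame:
    if isinstance(meta, pd.DataFrame):
        return meta
    return pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in meta],
            "patient_id": [m.patient_id for m in meta],
            "timepoint": [m.timepoint for m in meta],
            "arm": [m.arm for m in meta],
            "phenotype": [m.phenotype for m in meta],
        }
    )


def match_clonotypes(
    assignment: ClonotypeAssignment, meta
) -> dict[str, SharedClonotypeSet]:
    """Per-arm sharing of clonotypes between the pre and post timepoints.

    A clonotype is shared for a patient iff it has at least one member cell
    at both of that patient's timepoints; shared cells are the member cells
    of shared clonotypes at either timepoint.  Patients lacking a timepoint
    are excluded with a warning.
    """
    df = _meta_frame(meta)
    df = df[df["cell_id"].isin(assignment.cell_to_clonotype)].copy()
    df["clonotype_id"] = df["cell_id"].map(assignment.cell_to_clonotype)
    out: dict[str, SharedClonotypeSet] = {}
    for arm, arm_df in df.groupby("arm", sort=False):
        result = SharedClonotypeSet(arm=arm)
        for patient, pat_df in arm_df.groupby("patient_id", sort=False):
            tps = set(pat_df["timepoint"])
            if not {"pre", "post"} <= tps:
                logger.warning(
                    "patient %s (%s) lacks timepoint(s) %s; excluded from tracking",
                    patient, arm, sorted({"pre", "post"} - tps),
                )
                continue
            result.total_cells += len(pat_df)
            pre = pat_df[pat_df["timepoint"] == "pre"]
            post = pat_df[pat_df["timepoint"] == "post"]
            pre_ids = set(pre["clonotype_id"])
            post_ids = set(post["clonotype_id"])
            shared = pre_ids & post_ids
            result.shared |= shared
            result.pre_only |= pre_ids - post_ids
            result.post_only |= post_ids - pre_ids
            in_shared = pat_df["clonotype_id"].isin(shared)
            result.n_shared_cells += int(in_shared.sum())
            for cid in shared:
                result.tracks[(patient, cid)] = (
                    list(pre.loc[pre["clonotype_id"] == cid, "phenotype"]),
                    list(post.loc[post["clonotype_id"] == cid, "phenotype"]),
                )
        out[arm] = result
        logger.info(
            "%s: %d shared clonotypes, %d/%d shared cells (%.2f%%)",
            arm, result.n_shared_clonotypes, result.n_shared_cells,
            result.total_cells, 100 * result.shared_cell_fraction,
        )
    return out


def shared_fraction_test(
    sets: dict[str, SharedClonotypeSet], reference_arm: str = "placebo"
) -> dict[str, TestResult]:
    """Chi-squared tests of shared-cell proportions between arms.

    Each non-reference arm is tested against the reference on the 2x2
    table (shared vs non-shared cells x arm); the key 'global' holds the
    r x 2 test over all arms.
    """
    if len(sets) < 2:
        raise ValueError("need at least two arms")
    rows = {}
    for arm, s in sets.items():
        if s.total_cells == 0:
            raise ValueError(f"arm {arm!r} has no tracked cells")
        rows[arm] = [s.n_shared_cells, s.total_cells - s.n_shared_cells]
    results: dict[str, TestResult] = {}
    ref = rows[reference_arm]
    for arm, row in rows.items():
        if arm == reference_arm:
            continue
        table = ContingencyTable(
            np.array([row, ref]), row_labels=[arm, reference_arm],
            col_labels=["shared", "non_shared"],
        )
        results[arm] = chi2_independence(table)
    results["global"] = chi2_independence(
        ContingencyTable(
            np.array(list(rows.values())),
            row_labels=list(rows),
            col_labels=["shared", "non_shared"],
        )
    )
    return results


def _collapse(phenos: list[str], collapse: dict[str, str | None]) -> list[str]:
    out = []
    for p in phenos:
        c = collapse.get(p, p)
        if c is not None:
            out.append(c)
    return out


def _collapsed_labels(collapse: dict[str, str | None]) -> list[str]:
    seen: list[str] = []
    for v in collapse.values():
        if v is not None and v not in seen:
            seen.append(v)
    return seen


def build_transition_table(
    shared: SharedClonotypeSet,
    restrict_to: set[str] | None = frozenset({"Treg"}),
    collapse: dict[str, str | None] = DEFAULT_CD4_COLLAPSE,
) -> TransitionTable:
    """Pre/post phenotype count table over tracked clonotypes.

    Phenotypes are collapsed with ``collapse`` (labels mapped to None are
    dropped).  With ``restrict_to`` set, only clonotypes with at least one
    cell of a restricted phenotype at either timepoint contribute.  Row 1
    counts pre cells, row 2 post cells, by collapsed phenotype.
    """
    labels = _collapsed_labels(collapse)
    pre_counts = {k: 0 for k in labels}
    post_counts = {k: 0 for k in labels}
    n_tracked = 0
    for (patient, cid), (pre, post) in shared.tracks.items():
        pre_c = _collapse(pre, collapse)
        post_c = _collapse(post, collapse)
        if not (pre_c or post_c):
            continue
        if restrict_to is not None and not (set(pre_c) | set(post_c)) & set(restrict_to):
            continue
        n_tracked += 1
        for p in pre_c:
            pre_counts[p] += 1
        for p in post_c:
            post_counts[p] += 1
    counts = np.array([[pre_counts[k] for k in labels], [post_counts[k] for k in labels]])
    if n_tracked == 0 or counts.sum() == 0:
        return TransitionTable(None, shared.arm,
                               frozenset(restrict_to) if restrict_to else None, 0)
    table = ContingencyTable(counts, row_labels=["pre", "post"], col_labels=labels)
    return TransitionTable(table, shared.arm,
                           frozenset(restrict_to) if restrict_to else None, n_tracked)


def transition_significance(table: TransitionTable) -> float:
    """Exact Fisher p-value of the transition table (all-zero columns dropped).

    An empty table, or one with fewer than two non-empty phenotype columns,
    is maximally compatible with no phenotype shift and returns p = 1.
    """
    if table.empty:
        return 1.0
    counts = table.table.counts
    counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2 or np.any(counts.sum(axis=1) == 0):
        return 1.0
    return fisher_exact_rxc(
        ContingencyTable(counts, row_labels=["pre", "post"])
    )


def empirical_transition_matrix(
    shared: SharedClonotypeSet,
    weighting: str = "per-clonotype",
    collapse: dict[str, str | None] = DEFAULT_CD4_COLLAPSE,
) -> TransitionMatrix:
    """Empirical phenotype transition matrix from shared clonotypes.

    Every (pre-cell, post-cell) pair within a shared clonotype contributes
    one phenotype transition.  With ``weighting='per-clonotype'`` each pair
    carries weight 1/(n_pre * n_post) so each clonotype contributes total
    weight 1 (the matrix is then invariant to duplicating all cells of a
    clonotype); with ``'per-pair'`` each pair carries weight 1.  Rows are
    normalized to sum to 1; source phenotypes never observed at pre are
    left undefined (NaN).
    """
    if weighting not in ("per-clonotype", "per-pair"):
        raise ValueError(f"unknown weighting {weighting!r}")
    labels = _collapsed_labels(collapse)
    idx = {k: i for i, k in enumerate(labels)}
    acc = np.zeros((len(labels), len(labels)))
    for (patient, cid), (pre, post) in shared.tracks.items():
        pre_c = _collapse(pre, collapse)
        post_c = _collapse(post, collapse)
        if not pre_c or not post_c:
            continue
        w = 1.0 / (len(pre_c) * len(post_c)) if weighting == "per-clonotype" else 1.0
        for p in pre_c:
            for q in post_c:
                acc[idx[p], idx[q]] += w
    counts = pd.DataFrame(acc, index=labels, columns=labels)
    row_sums = acc.sum(axis=1)
    matrix = np.full_like(acc, np.nan)
    defined = row_sums > 0
    matrix[defined] = acc[defined] / row_sums[defined, None]
    undefined = [labels[i] for i in range(len(labels)) if not defined[i]]
    if undefined:
        logger.warning("%s: no tracked pre cells for source phenotype(s) %s",
                       shared.arm, undefined)
    return TransitionMatrix(
        matrix=pd.DataFrame(matrix, index=labels, columns=labels),
        counts=counts,
        weighting=weighting,
        arm=shared.arm,
        undefined_rows=undefined,
    )


def export_sankey(tm: TransitionMatrix) -> pd.DataFrame:
    """(source, target, weight) link list of the unnormalized transition flow."""
    rows = [
        {"source": src, "target": tgt, "weight": float(tm.counts.loc[src, tgt])}
        for src in tm.counts.index
        for tgt in tm.counts.columns
        if tm.counts.loc[src, tgt] > 0
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
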