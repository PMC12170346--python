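"""Clonotype definition by CDR3 alignment distance over both receptor arms.

Cells are first deduplicated to unique (alpha-CDR3, beta-CDR3) receptors.
Two receptors are connected when their chain distances fall within the
cutoff (by default both arms must be within the cutoff; an OR and a
combined-sum variant are available).  Clonotypes are the connected
components of this receptor graph, mapped back to cells.  Transitive
merging means members of one clonotype can individually be further apart
than the cutoff; this is inherent to the component formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .alignment import AlignmentParams, neighbor_pairs, receptor_distance
from .io import CellReceptor

logger = logging.getLogger(__name__)


@dataclass
class ClonotypeAssignment:
    """Partition of QC-passing cells into clonotypes."""

    cell_to_clonotype: dict[str, str]
    members: dict[str, list[str]]  # clonotype id -> cell ids
    representative: dict[str, tuple[str, str]]  # clonotype id -> (alpha, beta) CDR3
    patients: dict[str, set[str]] = field(default_factory=dict)
    phenotype_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[str, int]:
        return {cid: len(m) for cid, m in self.members.items()}

    def size_of_cell(self, cell_id: str) -> int:
        return len(self.members[self.cell_to_clonotype[cell_id]])

    def is_private(self, clonotype_id: str) -> bool:
        return len(self.patients.get(clonotype_id, set())) <= 1

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_id": cell, "clonotype_id": cid, "clonotype_size": len(self.members[cid])}
            for cid, cells in self.members.items()
            for cell in cells
        ]
        return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _chain_adjacency(
    seqs: list[str], params: AlignmentParams
) -> dict[int, dict[int, int]]:
    """Sparse symmetric adjacency {i: {j: distance}} within the cutoff."""
    adj: dict[int, dict[int, int]] = {i: {} for i in range(len(seqs))}
    if len(seqs) > 1:
        ii, jj, dd = neighbor_pairs(seqs, params)
        for i, j, d in zip(ii, jj, dd):
            adj[int(i)][int(j)] = int(d)
            adj[int(j)][int(i)] = int(d)
    return adj


def define_clonotype_clusters(
    cells: Sequence[CellReceptor],
    params: AlignmentParams | None = None,
    arms: str = "all",
) -> ClonotypeAssignment:
    """Cluster cells into clonotypes by paired CDR3 alignment distance.

    ``arms='all'`` requires both alpha and beta distances within the cutoff
    (the default, strict reading of "all receptor arms"); ``arms='any'``
    requires either; ``arms='combined'`` requires d_alpha + d_beta <= cutoff.
    V-gene matching is not enforced.  Clonotype ids are deterministic:
    sorted by descending size, ties broken by the lexicographically
    smallest member beta CDR3.
    """
    if not cells:
        raise ValueError("no cells supplied")
    if arms not in ("all", "any", "combined"):
        raise ValueError(f"unknown arms mode {arms!r}")
    params = params or AlignmentParams()

    # deduplicate to unique (alpha, beta) receptors
    receptor_of: dict[tuple[str, str], int] = {}
    receptor_cells: list[list[str]] = []
    receptor_keys: list[tuple[str, str]] = []
    for cell in cells:
        key = (cell.alpha.cdr3_aa, cell.beta.cdr3_aa)
        idx = receptor_of.get(key)
        if idx is None:
            idx = len(receptor_keys)
            receptor_of[key] = idx
            receptor_keys.append(key)
            receptor_cells.append([])
        receptor_cells[idx].append(cell.cell_id)
    n_rec = len(receptor_keys)
    logger.info("clonotyping %d cells -> %d unique receptors", len(cells), n_rec)

    uf = _UnionFind(n_rec)
    if params.cutoff > 0:
        alpha_seqs = sorted({a for a, _ in receptor_keys})
        beta_seqs = sorted({b for _, b in receptor_keys})
        a_index = {s: i for i, s in enumerate(alpha_seqs)}
        b_index = {s: i for i, s in enumerate(beta_seqs)}
        a_adj = _chain_adjacency(alpha_seqs, params)
        b_adj = _chain_adjacency(beta_seqs, params)
        rec_a = [a_index[a] for a, _ in receptor_keys]
        rec_b = [b_index[b] for _, b in receptor_keys]
        by_alpha: dict[int, list[int]] = {}
        for r, ia in enumerate(rec_a):
            by_alpha.setdefault(ia, []).append(r)

        def _link(r: int, s: int, da: int) -> None:
            db = 0 if rec_b[r] == rec_b[s] else b_adj[rec_b[r]].get(rec_b[s])
            if arms == "all":
                ok = db is not None
            elif arms == "any":
                ok = da <= params.cutoff or db is not None
            else:  # combined
                ok = db is not None and da + db <= params.cutoff
            if ok:
                uf.union(r, s)

        for ia, group in by_alpha.items():
            # receptors sharing an identical alpha chain (d_alpha = 0)
            for x in range(len(group)):
                for y in range(x + 1, len(group)):
                    _link(group[x], group[y], 0)
            # receptors whose alpha chains are within the cutoff
            for ja, da in a_adj[ia].items():
                if ja < ia:
                    continue
                for r in group:
                    for s in by_alpha.get(ja, ()):
                        _link(r, s, da)
        if arms == "any":
            # beta-side identity/closeness can also link receptors with
            # distant alphas
            by_beta: dict[int, list[int]] = {}
            for r, ib in enumerate(rec_b):
                by_beta.setdefault(ib, []).append(r)
            for ib, group in by_beta.items():
                for x in range(len(group)):
                    for y in range(x + 1, len(group)):
                        uf.union(group[x], group[y])
                for jb in b_adj[ib]:
                    if jb < ib:
                        continue
                    for r in group:
                        for s in by_beta.get(jb, ()):
                            uf.union(r, s)

    comp_members: dict[int, list[int]] = {}
    for r in range(n_rec):
        comp_members.setdefault(uf.find(r), []).append(r)

    clusters = []
    for recs in comp_members.values():
        member_cells = [c for r in recs for c in receptor_cells[r]]
        rep_beta = min(receptor_keys[r][1] for r in recs)
        rep = min((receptor_keys[r] for r in recs), key=lambda k: (k[1], k[0]))
        clusters.append((len(member_cells), rep_beta, rep, member_cells))
    clusters.sort(key=lambda t: (-t[0], t[1]))

    meta_by_cell = {c.cell_id: c.meta for c in cells}
    width = max(4, len(str(len(clusters))))
    assignment = ClonotypeAssignment({}, {}, {})
    for rank, (size, _, rep, member_cells) in enumerate(clusters):
        cid = f"ct{rank:0{width}d}"
        assignment.members[cid] = sorted(member_cells)
        assignment.representative[cid] = rep
        pheno: dict[str, int] = {}
        pats: set[str] = set()
        for cell in member_cells:
            assignment.cell_to_clonotype[cell] = cid
            m = meta_by_cell[cell]
            pats.add(m.patient_id)
            pheno[m.phenotype] = pheno.get(m.phenotype, 0) + 1
        assignment.patients[cid] = pats
        assignment.phenotype_counts[cid] = pheno
    logger.info("clonotyping produced %d clonotypes (largest size %d)",
                len(clusters), clusters[0][0] if clusters else 0)
    return assignment


_COMPARTMENTS = {
    "all": None,
    "CD4": ("Treg", "CD4_naive", "CD4_Tcm", "CD4_Tem"),
    "CD8": ("CD8_naive", "CD8_Tcm", "CD8_Tem", "CD8_Temra"),
}


def clonotype_size_spectrum(
    assignment: ClonotypeAssignment,
    meta,
    compartment: str = "all",
) -> pd.DataFrame:
    """Clonotype-size frequency table, optionally within the CD4 or CD8 compartment.

    Sizes are recomputed within the compartment (the number of compartment
    cells per clonotype); clonotypes without compartment cells are ignored.
    """
    if compartment not in _COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}; use all, CD4 or CD8")
    allowed = _COMPARTMENTS[compartment]
    pheno_by_cell = {m.cell_id: m.phenotype for m in meta}
    sizes = []
    for cid, cells in assignment.members.items():
        if allowed is None:
            n = len(cells)
        else:
            n = sum(1 for c in cells if pheno_by_cell.get(c) in allowed)
        if n > 0:
            sizes.append(n)
    spectrum = pd.Series(sizes).value_counts().sort_index()
    df = spectrum.rename_axis("clonotype_size").rename("n_clonotypes").reset_index()
    df.attrs["min_size"] = int(df["clonotype_size"].min()) if len(df) else 0
    df.attrs["max_size"] = int(df["clonotype_size"].max()) if len(df) else 0
    return df


def export_clonotype_network(
    assignment: ClonotypeAssignment,
    params: AlignmentParams | None = None,
    min_size: int = 15,
    related_cutoff: int | None = None,
) -> nx.Graph:
    """Graph of large clonotypes; edges join clonotypes whose representative
    receptors are within ``related_cutoff`` on both arms ("closely related").

    Since clustering already merges receptors within the clonotype cutoff,
    relatedness between distinct clonotypes is judged at a wider margin
    (twice the clonotype cutoff by default).
    """
    params = params or AlignmentParams()
    if related_cutoff is None:
        related_cutoff = 2 * params.cutoff
    graph = nx.Graph()
    big = [cid for cid, m in assignment.members.items() if len(m) >= min_size]
    for cid in big:
        graph.add_node(
            cid,
            size=len(assignment.members[cid]),
            patients=",".join(sorted(assignment.patients.get(cid, set()))),
            private=assignment.is_private(cid),
        )
    for i in range(len(big)):
        ai, bi = assignment.representative[big[i]]
        for j in range(i + 1, len(big)):
            aj, bj = assignment.representative[big[j]]
            if (
                receptor_distance(ai, aj, params) <= related_cutoff
                and receptor_distance(bi, bj, params) <= related_cutoff
            ):
                graph.add_edge(big[i], big[j])
    return graph
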