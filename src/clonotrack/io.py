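"""Reading and writing TCR chain tables and the paired-chain QC funnel.

Chain tables are accepted either as AIRR Rearrangement TSV (columns
``cell_id, locus, junction_aa, v_call, j_call, productive``) or as 10x
``filtered_contig_annotations.csv`` (columns ``barcode, chain, cdr3,
v_gene, j_gene, productive, umis``).  QC keeps cells with exactly one
productive TRA and one productive TRB chain, classifies the rest
(multi-chain / orphan / non-productive-only) and removes invariant
(MAIT/iNKT-like) receptors.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

PHENOTYPES = (
    "Treg",
    "CD4_naive",
    "CD4_Tcm",
    "CD4_Tem",
    "CD8_naive",
    "CD8_Tcm",
    "CD8_Tem",
    "CD8_Temra",
)

ARMS = ("placebo", "IL2_1.5", "IL2_2.5")
TIMEPOINTS = ("pre", "post")

AIRR_COLUMNS = ["cell_id", "locus", "junction_aa", "junction", "v_call", "j_call",
                "productive", "duplicate_count"]
_AIRR_REQUIRED = ["cell_id", "locus", "junction_aa", "v_call", "j_call", "productive"]
_TENX_REQUIRED = ["barcode", "chain", "cdr3", "v_gene", "j_gene", "productive"]


@dataclass
class ChainRecord:
    """One sequenced TCR chain of one cell."""

    cell_id: str
    locus: str  # TRA, TRB or other
    cdr3_aa: str
    v_gene: str
    j_gene: str
    productive: bool
    cdr3_nt: str = ""
    umis: int = 0

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            self.locus = self.locus if self.locus in ("TRA", "TRB") else "other"
        if self.productive and not AA_RE.match(self.cdr3_aa or ""):
            raise ValueError(
                f"productive chain of cell {self.cell_id!r} has invalid CDR3 "
                f"amino-acid sequence {self.cdr3_aa!r}"
            )


@dataclass
class CellMeta:
    """Sample-level annotation of one cell."""

    cell_id: str
    patient_id: str
    timepoint: str
    arm: str
    phenotype: str


@dataclass
class CellReceptor:
    """A QC-passing cell: one productive alpha and one productive beta chain."""

    cell_id: str
    alpha: ChainRecord
    beta: ChainRecord
    meta: CellMeta

    def __post_init__(self) -> None:
        if self.alpha.locus != "TRA" or self.beta.locus != "TRB":
            raise ValueError("alpha/beta chains must have loci TRA/TRB")
        if not (self.alpha.cdr3_aa and self.beta.cdr3_aa):
            raise ValueError("both CDR3s must be non-empty")


@dataclass
class QCReport:
    """Counts of the QC funnel; the categories partition the input cells."""

    n_input_cells: int = 0
    n_single_paired: int = 0
    n_multi_chain: int = 0
    n_orphan: int = 0
    n_nonproductive_only: int = 0
    n_invariant_removed: int = 0
    n_no_metadata: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        n = max(self.n_input_cells, 1)
        return {
            "single_paired": self.n_single_paired / n,
            "multi_chain": self.n_multi_chain / n,
            "orphan": self.n_orphan / n,
            "nonproductive_only": self.n_nonproductive_only / n,
            "invariant_removed": self.n_invariant_removed / n,
            "no_metadata": self.n_no_metadata / n,
        }

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["fractions"] = self.fractions
        Path(path).write_text(json.dumps(payload, indent=2))


# Default invariant-receptor rules: alpha V/J combinations of MAIT and iNKT
# cells.  Each rule is (V prefix, allowed J prefixes).
DEFAULT_INVARIANT_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("TRAV1-2", ("TRAJ33", "TRAJ20", "TRAJ12")),
    ("TRAV10", ("TRAJ18",)),
)


def _parse_bool(v) -> bool:
    return str(v).strip().lower() in ("true", "t", "1", "yes")


def read_airr(path: str | Path) -> list[ChainRecord]:
    """Read an AIRR Rearrangement TSV into chain records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR file {path} is missing mandatory column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ChainRecord(
                cell_id=row.cell_id,
                locus=row.locus,
                cdr3_aa=row.junction_aa,
                cdr3_nt=getattr(row, "junction", ""),
                v_gene=row.v_call,
                j_gene=row.j_call,
                productive=_parse_bool(row.productive),
                umis=int(getattr(row, "duplicate_count", 0) or 0),
            )
        )
    return records


def read_10x_contigs(path: str | Path) -> list[ChainRecord]:
    """Read a 10x filtered_contig_annotations.csv into chain records."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _TENX_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"10x contig file {path} is missing mandatory column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ChainRecord(
                cell_id=row.barcode,
                locus=row.chain,
                cdr3_aa=row.cdr3,
                cdr3_nt=getattr(row, "cdr3_nt", ""),
                v_gene=row.v_gene,
                j_gene=row.j_gene,
                productive=_parse_bool(row.productive),
                umis=int(getattr(row, "umis", 0) or 0),
            )
        )
    return records


def chains_to_frame(chains: Iterable[ChainRecord]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": c.cell_id,
            "locus": c.locus,
            "junction_aa": c.cdr3_aa,
            "junction": c.cdr3_nt,
            "v_call": c.v_gene,
            "j_call": c.j_gene,
            "productive": "T" if c.productive else "F",
            "duplicate_count": c.umis,
        }
        for c in chains
    ]
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_airr(chains: Iterable[ChainRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write chain records as AIRR Rearrangement TSV."""
    df = chains if isinstance(chains, pd.DataFrame) else chains_to_frame(chains)
    df.to_csv(path, sep="\t", index=False)


def chains_from_frame(df: pd.DataFrame) -> list[ChainRecord]:
    """Convert an AIRR-schema DataFrame (e.g. generator output) to records."""
    missing = [c for c in _AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"chain table is missing mandatory column(s): {missing}")
    return [
        ChainRecord(
            cell_id=row.cell_id,
            locus=row.locus,
            cdr3_aa=row.junction_aa,
            cdr3_nt=str(getattr(row, "junction", "") or ""),
            v_gene=row.v_call,
            j_gene=row.j_call,
            productive=_parse_bool(row.productive),
            umis=int(getattr(row, "duplicate_count", 0) or 0),
        )
        for row in df.itertuples(index=False)
    ]


def meta_from_frame(df: pd.DataFrame) -> list[CellMeta]:
    """Convert a metadata DataFrame to records."""
    return [
        CellMeta(row.cell_id, row.patient_id, row.timepoint, row.arm, row.phenotype)
        for row in df.itertuples(index=False)
    ]


def read_cell_meta(path: str | Path) -> list[CellMeta]:
    """Read a cell metadata TSV (cell_id, patient_id, timepoint, arm, phenotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cell_id", "patient_id", "timepoint", "arm", "phenotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} is missing column(s): {missing}")
    return [
        CellMeta(row.cell_id, row.patient_id, row.timepoint, row.arm, row.phenotype)
        for row in df.itertuples(index=False)
    ]


def write_cell_meta(meta: Iterable[CellMeta] | pd.DataFrame, path: str | Path) -> None:
    if not isinstance(meta, pd.DataFrame):
        meta = pd.DataFrame([asdict(m) for m in meta])
    meta.to_csv(path, sep="\t", index=False)


def _is_invariant(alpha: ChainRecord, rules) -> bool:
    for v_prefix, j_prefixes in rules:
        if alpha.v_gene.startswith(v_prefix) and any(
            alpha.j_gene.startswith(j) for j in j_prefixes
        ):
            return True
    return False


def qc_single_paired(
    chains: Sequence[ChainRecord],
    meta: Sequence[CellMeta],
    invariant_rules=DEFAULT_INVARIANT_RULES,
    scope_barcodes: bool = False,
) -> tuple[list[CellReceptor], QCReport]:
    """Apply the single-paired-chain QC funnel.

    A cell is kept iff it has exactly one productive TRA and one productive
    TRB chain (extra non-productive chains are ignored); otherwise it is
    classified as multi_chain (>= 2 productive chains of the same locus),
    orphan (productive chains of only one locus) or nonproductive_only.
    Kept cells whose alpha V/J matches an invariant-receptor rule are then
    removed.  ``scope_barcodes`` prefixes cell ids with patient_timepoint
    to make sample-scoped barcodes globally unique.
    """
    if not chains:
        raise ValueError("no chains supplied")
    meta_by_cell = {m.cell_id: m for m in meta}

    by_cell: dict[str, list[ChainRecord]] = {}
    for c in chains:
        by_cell.setdefault(c.cell_id, []).append(c)

    report = QCReport(n_input_cells=len(by_cell))
    kept: list[CellReceptor] = []
    for cell_id, cell_chains in by_cell.items():
        m = meta_by_cell.get(cell_id)
        if m is None:
            logger.warning("cell %s has no metadata; dropped", cell_id)
            report.n_no_metadata += 1
            continue
        prod = [c for c in cell_chains if c.productive]
        n_tra = sum(1 for c in prod if c.locus == "TRA")
        n_trb = sum(1 for c in prod if c.locus == "TRB")
        if n_tra >= 2 or n_trb >= 2:
            report.n_multi_chain += 1
        elif n_tra == 1 and n_trb == 1:
            alpha = next(c for c in prod if c.locus == "TRA")
            beta = next(c for c in prod if c.locus == "TRB")
            if _is_invariant(alpha, invariant_rules):
                logger.debug("cell %s removed as invariant (%s/%s)", cell_id, alpha.v_gene, alpha.j_gene)
                report.n_invariant_removed += 1
                continue
            if scope_barcodes:
                cell_id = f"{m.patient_id}_{m.timepoint}_{cell_id}"
                alpha = ChainRecord(cell_id, "TRA", alpha.cdr3_aa, alpha.v_gene,
                                    alpha.j_gene, True, alpha.cdr3_nt, alpha.umis)
                beta = ChainRecord(cell_id, "TRB", beta.cdr3_aa, beta.v_gene,
                                   beta.j_gene, True, beta.cdr3_nt, beta.umis)
                m = CellMeta(cell_id, m.patient_id, m.timepoint, m.arm, m.phenotype)
            report.n_single_paired += 1
            kept.append(CellReceptor(cell_id, alpha, beta, m))
        elif n_tra + n_trb >= 1:
            report.n_orphan += 1
        else:
            report.n_nonproductive_only += 1
    logger.info(
        "QC: %d input cells -> %d single-paired (%.1f%%), %d multi-chain, "
        "%d orphan, %d non-productive, %d invariant removed",
        report.n_input_cells, report.n_single_paired,
        100 * report.fractions["single_paired"], report.n_multi_chain,
        report.n_orphan, report.n_nonproductive_only, report.n_invariant_removed,
    )
    return kept, report


def gene_usage(cells: Sequence[CellReceptor]) -> dict[str, pd.DataFrame]:
    """V/J gene usage frequencies and pairing landscapes.

    Returns per-locus V and J frequency tables (descending), V-J pairing
    counts per locus and the alpha-beta V-gene pairing counts.
    """
    if not cells:
        raise ValueError("no cells supplied")
    df = pd.DataFrame(
        {
            "v_alpha": [c.alpha.v_gene for c in cells],
            "j_alpha": [c.alpha.j_gene for c in cells],
            "v_beta": [c.beta.v_gene for c in cells],
            "j_beta": [c.beta.j_gene for c in cells],
        }
    )
    out: dict[str, pd.DataFrame] = {}
    for col in ("v_alpha", "j_alpha", "v_beta", "j_beta"):
        freq = df[col].value_counts(normalize=True).rename("frequency").to_frame()
        out[col] = freq
    out["vj_alpha_pairing"] = df.groupby(["v_alpha", "j_alpha"]).size().rename("count").reset_index()
    out["vj_beta_pairing"] = df.groupby(["v_beta", "j_beta"]).size().rename("count").reset_index()
    out["alpha_beta_pairing"] = df.groupby(["v_alpha", "v_beta"]).size().rename("count").reset_index()
    return out
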