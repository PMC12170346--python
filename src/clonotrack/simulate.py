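"""Synthetic longitudinal paired scTCR + phenotype cohort generator.

Emulates a three-arm placebo-controlled low-dose IL-2 trial design: 16
patients (placebo n=4, 1.5 MIU n=6, 2.5 MIU n=6), two timepoints each,
with a heavy-tailed clonotype-size law, arm-dependent regulatory-T-cell
proportions, clonotype persistence between timepoints, phenotype
transition kernels, planted CDR3 motif families, planted differential
expression and configurable QC defects.  Every planted quantity is
recorded in a GroundTruth object so pipeline stages can be tested as
parameter-recovery problems.

All randomness flows from one seeded generator; identical configs and
seeds give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PHENOTYPES

logger = logging.getLogger(__name__)

# position-independent amino-acid frequencies for CDR3 interiors
# (glycine/serine-rich, tryptophan/cysteine-poor; normalized at use)
_AA_FREQS = {
    "A": 0.060, "C": 0.010, "D": 0.050, "E": 0.060, "F": 0.030,
    "G": 0.110, "H": 0.020, "I": 0.040, "K": 0.040, "L": 0.080,
    "M": 0.020, "N": 0.040, "P": 0.050, "Q": 0.060, "R": 0.065,
    "S": 0.120, "T": 0.060, "V": 0.060, "W": 0.015, "Y": 0.040,
}
_AA_LETTERS = np.array(list(_AA_FREQS))
_AA_PROBS = np.array(list(_AA_FREQS.values()))
_AA_PROBS = _AA_PROBS / _AA_PROBS.sum()

# relative abundance of the non-regulatory phenotypes
_NONTREG_WEIGHTS = {
    "CD4_naive": 0.24, "CD4_Tcm": 0.20, "CD4_Tem": 0.14,
    "CD8_naive": 0.12, "CD8_Tcm": 0.09, "CD8_Tem": 0.11, "CD8_Temra": 0.10,
}

_TRAV_POOL = tuple(f"TRAV{i}" for i in range(2, 30) if i != 10)
_TRAJ_POOL = tuple(f"TRAJ{i}" for i in range(1, 40) if i not in (12, 18, 20, 33))
_TRBV_POOL = tuple(f"TRBV{i}" for i in range(2, 31))
_TRBJ_POOL = tuple(f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7))

_ALPHA_LENGTHS = (10, 11, 12, 13, 14, 15, 16, 17)
_ALPHA_LENGTH_W = (1, 2, 4, 6, 6, 4, 2, 1)
_BETA_LENGTHS = (11, 12, 13, 14, 15, 16, 17, 18, 19)
_BETA_LENGTH_W = (1, 2, 4, 6, 7, 6, 4, 2, 1)


def _build_kernel(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=list(PHENOTYPES), columns=list(PHENOTYPES))
    for src, dests in rows.items():
        total = sum(dests.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"kernel row {src} sums to {total}")
        for dst, p in dests.items():
            mat.loc[src, dst] = p
    return mat


# Placebo: post-infarct inflammatory polarization - the regulatory
# compartment contracts toward effector/central memory.
PLACEBO_KERNEL = _build_kernel({
    "Treg": {"Treg": 0.15, "CD4_Tcm": 0.35, "CD4_Tem": 0.40, "CD4_naive": 0.10},
    "CD4_naive": {"CD4_naive": 0.70, "CD4_Tcm": 0.15, "CD4_Tem": 0.10, "Treg": 0.05},
    "CD4_Tcm": {"CD4_Tcm": 0.70, "CD4_Tem": 0.20, "CD4_naive": 0.05, "Treg": 0.05},
    "CD4_Tem": {"CD4_Tem": 0.85, "CD4_Tcm": 0.10, "CD4_naive": 0.03, "Treg": 0.02},
    "CD8_naive": {"CD8_naive": 0.80, "CD8_Tcm": 0.15, "CD8_Tem": 0.05},
    "CD8_Tcm": {"CD8_Tcm": 0.75, "CD8_Tem": 0.20, "CD8_naive": 0.05},
    "CD8_Tem": {"CD8_Tem": 0.80, "CD8_Temra": 0.15, "CD8_Tcm": 0.05},
    "CD8_Temra": {"CD8_Temra": 0.90, "CD8_Tem": 0.10},
})

# IL-2 arms: the regulatory phenotype is retained and mildly recruited into.
IL2_KERNEL = _build_kernel({
    "Treg": {"Treg": 0.80, "CD4_Tcm": 0.10, "CD4_Tem": 0.05, "CD4_naive": 0.05},
    "CD4_naive": {"CD4_naive": 0.65, "Treg": 0.10, "CD4_Tcm": 0.15, "CD4_Tem": 0.10},
    "CD4_Tcm": {"CD4_Tcm": 0.70, "Treg": 0.10, "CD4_Tem": 0.15, "CD4_naive": 0.05},
    "CD4_Tem": {"CD4_Tem": 0.80, "Treg": 0.05, "CD4_Tcm": 0.12, "CD4_naive": 0.03},
    "CD8_naive": {"CD8_naive": 0.80, "CD8_Tcm": 0.15, "CD8_Tem": 0.05},
    "CD8_Tcm": {"CD8_Tcm": 0.75, "CD8_Tem": 0.20, "CD8_naive": 0.05},
    "CD8_Tem": {"CD8_Tem": 0.80, "CD8_Temra": 0.15, "CD8_Tcm": 0.05},
    "CD8_Temra": {"CD8_Temra": 0.90, "CD8_Tem": 0.10},
})


@dataclass(frozen=True)
class ArmConfig:
    """One treatment arm: patient count, regulatory-T-cell targets,
    between-timepoint persistence and the phenotype transition kernel."""

    n_patients: int
    treg_post: float
    shared_cell_fraction: float  # calibration target for persistence
    post_size_boost: float  # mean post-size multiplier of persisting clones
    kernel: pd.DataFrame


@dataclass(frozen=True)
class MotifFamilyConfig:
    motif: str
    n_members: int
    label: str = "expanded_Treg"


@dataclass(frozen=True)
class ExpressionConfig:
    n_genes: int = 2000
    n_de_genes: int = 20
    de_log2fc: float = 1.0  # alternating sign across the planted genes
    de_base_mean: float = 5.0  # marker-level baseline for the planted genes
    base_mean_log: float = float(np.log(0.25))
    base_mean_sigma: float = 1.0
    lib_sigma: float = 0.3
    target_sum: float = 1000.0


def default_arms() -> dict[str, ArmConfig]:
    """The trial's arm structure with arm-dependent regulatory-cell
    proportions (pre 2%; post 4/6/9%) and clonotype-sharing targets
    (1.5 / 7.1 / 3.5% of cells in clonotypes seen at both timepoints)."""
    return {
        "placebo": ArmConfig(4, treg_post=0.04, shared_cell_fraction=0.015,
                             post_size_boost=1.0, kernel=PLACEBO_KERNEL),
        "IL2_1.5": ArmConfig(6, treg_post=0.06, shared_cell_fraction=0.071,
                             post_size_boost=6.0, kernel=IL2_KERNEL),
        "IL2_2.5": ArmConfig(6, treg_post=0.09, shared_cell_fraction=0.035,
                             post_size_boost=6.0, kernel=IL2_KERNEL),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    cells_per_sample: int = 2500
    clone_geom_p: float = 0.7
    clone_size_trunc: int = 1000
    treg_pre: float = 0.02
    phenotype_noise: float = 0.05
    arms: dict[str, ArmConfig] = field(default_factory=default_arms)
    # clonotypes of these phenotypes persist preferentially (antigen- and
    # cytokine-engaged clones); calibration accounts for the multiplier
    persistence_multiplier: dict[str, float] = field(
        default_factory=lambda: {"Treg": 3.0}
    )
    qc_multi_rate: float = 0.006
    qc_orphan_rate: float = 0.05
    qc_nonproductive_rate: float = 0.02
    qc_invariant_rate: float = 0.004
    motif_families: tuple[MotifFamilyConfig, ...] = (
        MotifFamilyConfig("QDRG", 10),
        MotifFamilyConfig("SWGE", 10),
    )
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self) -> None:
        for name, rate in (
            ("treg_pre", self.treg_pre), ("phenotype_noise", self.phenotype_noise),
            ("qc_multi_rate", self.qc_multi_rate), ("qc_orphan_rate", self.qc_orphan_rate),
            ("qc_nonproductive_rate", self.qc_nonproductive_rate),
            ("qc_invariant_rate", self.qc_invariant_rate),
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        for arm, cfg in self.arms.items():
            if not 0.0 < cfg.treg_post < 1.0:
                raise ValueError(f"infeasible treg_post for arm {arm}")


@dataclass
class GroundTruth:
    """Planted parameters and per-cell/per-clonotype labels of one simulation."""

    clonotype_of_cell: dict[str, str] = field(default_factory=dict)
    base_phenotype_pre: dict[str, str] = field(default_factory=dict)
    base_phenotype_post: dict[str, str] = field(default_factory=dict)
    persisting: dict[str, set[str]] = field(default_factory=dict)  # patient -> clonotypes
    kernels: dict[str, pd.DataFrame] = field(default_factory=dict)
    persistence: dict[str, float] = field(default_factory=dict)  # arm -> base rate
    arm_of_patient: dict[str, str] = field(default_factory=dict)
    motif_members: dict[str, list[str]] = field(default_factory=dict)  # motif -> CDR3s
    expanded_cells: set[str] = field(default_factory=set)
    de_effects: dict[str, float] = field(default_factory=dict)
    qc_defects: dict[str, list[str]] = field(default_factory=dict)
    shared_cell_target: dict[str, float] = field(default_factory=dict)


def base_proportion_for_observed(target: float, noise: float, n_labels: int = 8) -> float:
    """Base-label proportion whose observed (noise-flipped) fraction is ``target``.

    Label noise flips a cell to a uniformly random other label with
    probability ``noise``; observed = base*(1-noise) + (1-base)*noise/(K-1).
    """
    k = n_labels - 1
    p = (target - noise / k) / (1.0 - noise - noise / k)
    return float(min(max(p, 0.0), 1.0))


def _phenotype_probs(treg_base: float) -> np.ndarray:
    probs = np.empty(len(PHENOTYPES))
    rest = np.array([_NONTREG_WEIGHTS[p] for p in PHENOTYPES[1:]])
    probs[0] = treg_base
    probs[1:] = (1.0 - treg_base) * rest / rest.sum()
    return probs


def calibrated_persistence(
    target_fraction: float,
    boost: float,
    treg_base: float,
    multiplier: dict[str, float],
) -> float:
    """Base persistence rate hitting an expected shared-cell fraction.

    With clonotype-level persistence rho * mult(phenotype), expected
    shared cells are rho * sum(pi * mult) * (1 + boost)/2 of all cells, so
    rho = 2 * target / ((1 + boost) * sum(pi * mult)).
    """
    probs = _phenotype_probs(treg_base)
    mean_mult = sum(
        p * multiplier.get(ph, 1.0) for p, ph in zip(probs, PHENOTYPES)
    )
    rho = 2.0 * target_fraction / ((1.0 + boost) * mean_mult)
    if rho >= 1.0:
        raise ValueError("persistence calibration exceeds 1; lower the target")
    return rho


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    interior = "".join(rng.choice(_AA_LETTERS, size=length - 2, p=_AA_PROBS))
    return "C" + interior + "F"


def _draw_length(rng, lengths, weights) -> int:
    w = np.asarray(weights, dtype=float)
    return int(rng.choice(lengths, p=w / w.sum()))


def naive_cdr3_set(n: int, seed: int | np.random.Generator = 0) -> list[str]:
    """Naive-repertoire CDR3beta sequences (background model for motif mining)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        _random_cdr3(rng, _draw_length(rng, _BETA_LENGTHS, _BETA_LENGTH_W))
        for _ in range(n)
    ]


def motif_family_cdr3s(
    motif: str, n: int, rng: np.random.Generator, max_shift: int = 3
) -> list[str]:
    """CDR3beta sequences carrying ``motif`` at a jittered interior position.

    The motif start varies by at most ``max_shift`` positions in trimmed
    (flank-removed) coordinates, and the motif always lies fully inside
    the trimmed interior.
    """
    out = []
    k = len(motif)
    for _ in range(n):
        length = int(rng.integers(k + 10, k + 14))  # room for flanks + jitter
        seq = _random_cdr3(rng, length)
        start = 3 + int(rng.integers(0, max_shift + 1))  # full-sequence coords
        seq = seq[:start] + motif + seq[start + k :]
        out.append(seq[:length])
    return out


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / (np.arange(n) + 2.0)
    return w / w.sum()


@dataclass
class _Clone:
    cid: str
    patient: str
    arm: str
    alpha: str
    beta: str
    va: str
    ja: str
    vb: str
    jb: str
    pre_size: int
    post_size: int
    base_pre: str | None
    base_post: str | None


def _sample_clone_sizes(rng, n_cells: int, p: float, trunc: int) -> list[int]:
    sizes = []
    total = 0
    while total < n_cells:
        s = min(int(rng.geometric(p)), trunc, n_cells - total)
        sizes.append(s)
        total += s
    return sizes


def _observe(base: str, rng, noise: float) -> str:
    if noise > 0 and rng.random() < noise:
        others = [p for p in PHENOTYPES if p != base]
        return others[int(rng.integers(len(others)))]
    return base


def simulate_study(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the full cohort; returns (AIRR chain table, cell metadata, truth).

    Per patient and timepoint: clonotype sizes are drawn from a truncated
    geometric law; each clonotype carries a base phenotype; persisting
    clonotypes are re-sampled at post with sizes inflated by the arm's
    expansion boost and base phenotypes evolved by the arm's transition
    kernel; observed cell phenotypes add uniform label noise.  QC defect
    cells (multi-chain, orphan, non-productive-only, invariant) are
    appended at configured rates.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    truth.kernels = {arm: cfg.kernel for arm, cfg in config.arms.items()}
    truth.shared_cell_target = {
        arm: cfg.shared_cell_fraction for arm, cfg in config.arms.items()
    }

    treg_base_pre = base_proportion_for_observed(config.treg_pre, config.phenotype_noise)
    pre_probs = _phenotype_probs(treg_base_pre)
    kernel_mats = {arm: cfg.kernel.to_numpy() for arm, cfg in config.arms.items()}
    pheno_index = {p: i for i, p in enumerate(PHENOTYPES)}

    for arm, cfg in config.arms.items():
        truth.persistence[arm] = calibrated_persistence(
            cfg.shared_cell_fraction, cfg.post_size_boost,
            treg_base_pre, config.persistence_multiplier,
        )

    used_cdr3: set[str] = set()

    def fresh_cdr3(lengths, weights) -> str:
        while True:
            seq = _random_cdr3(rng, _draw_length(rng, lengths, weights))
            if seq not in used_cdr3:
                used_cdr3.add(seq)
                return seq

    va_p, ja_p = _zipf_probs(len(_TRAV_POOL)), _zipf_probs(len(_TRAJ_POOL))
    vb_p, jb_p = _zipf_probs(len(_TRBV_POOL)), _zipf_probs(len(_TRBJ_POOL))

    clones: list[_Clone] = []
    patient_counter = 0
    for arm, cfg in config.arms.items():
        rho = truth.persistence[arm]
        kernel = kernel_mats[arm]
        for _ in range(cfg.n_patients):
            patient = f"P{patient_counter:02d}"
            patient_counter += 1
            truth.arm_of_patient[patient] = arm
            truth.persisting[patient] = set()
            patient_clones: list[_Clone] = []

            def new_clone(pre_size: int, post_size: int, base_pre, base_post) -> _Clone:
                clone = _Clone(
                    cid=f"{patient}:{len(patient_clones):05d}",
                    patient=patient, arm=arm,
                    alpha=fresh_cdr3(_ALPHA_LENGTHS, _ALPHA_LENGTH_W),
                    beta=fresh_cdr3(_BETA_LENGTHS, _BETA_LENGTH_W),
                    va=str(rng.choice(_TRAV_POOL, p=va_p)),
                    ja=str(rng.choice(_TRAJ_POOL, p=ja_p)),
                    vb=str(rng.choice(_TRBV_POOL, p=vb_p)),
                    jb=str(rng.choice(_TRBJ_POOL, p=jb_p)),
                    pre_size=pre_size, post_size=post_size,
                    base_pre=base_pre, base_post=base_post,
                )
                patient_clones.append(clone)
                return clone

            # pre repertoire
            for size in _sample_clone_sizes(
                rng, config.cells_per_sample, config.clone_geom_p, config.clone_size_trunc
            ):
                base = str(rng.choice(PHENOTYPES, p=pre_probs))
                new_clone(size, 0, base, None)

            # persistence and post evolution
            n_post_persist = 0
            treg_persist_base_cells = 0
            for clone in patient_clones:
                mult = config.persistence_multiplier.get(clone.base_pre, 1.0)
                if rng.random() >= min(1.0, rho * mult):
                    continue
                post_size = max(1, round(int(rng.geometric(config.clone_geom_p))
                                         * cfg.post_size_boost))
                post_size = min(post_size, config.clone_size_trunc,
                                config.cells_per_sample - n_post_persist)
                if post_size <= 0:
                    continue
                clone.post_size = post_size
                clone.base_post = str(
                    rng.choice(PHENOTYPES, p=kernel[pheno_index[clone.base_pre]])
                )
                truth.persisting[patient].add(clone.cid)
                n_post_persist += post_size
                if clone.base_post == "Treg":
                    treg_persist_base_cells += post_size

            # novel post clonotypes; their phenotype mix is solved so the
            # expected observed regulatory fraction hits the arm target
            n_novel_cells = config.cells_per_sample - n_post_persist
            treg_base_post = base_proportion_for_observed(
                cfg.treg_post, config.phenotype_noise
            )
            need_treg = max(
                0.0, treg_base_post * config.cells_per_sample - treg_persist_base_cells
            )
            novel_treg = min(0.9, need_treg / max(n_novel_cells, 1))
            novel_probs = _phenotype_probs(novel_treg)
            for size in _sample_clone_sizes(
                rng, n_novel_cells, config.clone_geom_p, config.clone_size_trunc
            ):
                base = str(rng.choice(PHENOTYPES, p=novel_probs))
                new_clone(0, size, None, base)

            clones.extend(patient_clones)

    _plant_motif_families(clones, config, truth, rng)

    chain_rows: list[dict] = []
    meta_rows: list[dict] = []
    cell_counter = 0

    def emit_cell(clone: _Clone, timepoint: str, base: str) -> str:
        nonlocal cell_counter
        cell_id = f"{clone.patient}_{timepoint}_c{cell_counter:06d}"
        cell_counter += 1
        truth.clonotype_of_cell[cell_id] = clone.cid
        observed = _observe(base, rng, config.phenotype_noise)
        meta_rows.append({
            "cell_id": cell_id, "patient_id": clone.patient,
            "timepoint": timepoint, "arm": clone.arm, "phenotype": observed,
        })
        for locus, cdr3, v, j in (
            ("TRA", clone.alpha, clone.va, clone.ja),
            ("TRB", clone.beta, clone.vb, clone.jb),
        ):
            chain_rows.append({
                "cell_id": cell_id, "locus": locus, "junction_aa": cdr3,
                "junction": "", "v_call": v, "j_call": j,
                "productive": "T", "duplicate_count": int(rng.integers(1, 20)),
            })
        return cell_id

    for clone in clones:
        for _ in range(clone.pre_size):
            emit_cell(clone, "pre", clone.base_pre)
        for _ in range(clone.post_size):
            emit_cell(clone, "post", clone.base_post)

        if clone.base_pre is not None:
            truth.base_phenotype_pre[clone.cid] = clone.base_pre
        if clone.base_post is not None:
            truth.base_phenotype_post[clone.cid] = clone.base_post

    meta = pd.DataFrame(meta_rows)
    chains = pd.DataFrame(chain_rows)
    chains, meta = _inject_qc_defects(chains, meta, config, truth, rng, fresh_cdr3)
    _mark_expanded_cells(meta, truth)
    logger.info(
        "simulated %d cells (%d chains) across %d patients",
        len(meta), len(chains), patient_counter,
    )
    return chains, meta, truth


def _plant_motif_families(clones, config, truth, rng) -> None:
    """Rewrite beta CDR3s of selected post regulatory clonotypes so each
    motif family shares its k-mer at jittered positions."""
    candidates = [
        c for c in clones if c.base_post == "Treg" and c.post_size >= 2
    ]
    rng.shuffle(candidates)
    taken = 0
    for family in config.motif_families:
        members = candidates[taken : taken + family.n_members]
        if len(members) < family.n_members:
            extra = [c for c in clones
                     if c.base_post == "Treg" and c not in members][: family.n_members - len(members)]
            members = members + extra
        taken += len(members)
        seqs = motif_family_cdr3s(family.motif, len(members), rng)
        for clone, seq in zip(members, seqs):
            clone.beta = seq
        truth.motif_members[family.motif] = [c.beta for c in members]


def _inject_qc_defects(chains, meta, config, truth, rng, fresh_cdr3):
    """Append defective cells at configured per-input-cell rates."""
    per_sample = meta.groupby(["patient_id", "timepoint", "arm"]).size()
    total_rate = (config.qc_multi_rate + config.qc_orphan_rate
                  + config.qc_nonproductive_rate + config.qc_invariant_rate)
    truth.qc_defects = {"multi_chain": [], "orphan": [], "nonproductive_only": [],
                        "invariant": []}
    chain_rows: list[dict] = []
    meta_rows: list[dict] = []
    counter = 0
    for (patient, timepoint, arm), n_clean in per_sample.items():
        n_input = round(n_clean / (1.0 - total_rate))
        plan = {
            "multi_chain": round(config.qc_multi_rate * n_input),
            "orphan": round(config.qc_orphan_rate * n_input),
            "nonproductive_only": round(config.qc_nonproductive_rate * n_input),
            "invariant": round(config.qc_invariant_rate * n_input),
        }
        for kind, n in plan.items():
            for _ in range(n):
                cell_id = f"{patient}_{timepoint}_qc{counter:06d}"
                counter += 1
                truth.qc_defects[kind].append(cell_id)
                meta_rows.append({
                    "cell_id": cell_id, "patient_id": patient,
                    "timepoint": timepoint, "arm": arm,
                    "phenotype": str(rng.choice(PHENOTYPES)),
                })
                alpha = fresh_cdr3(_ALPHA_LENGTHS, _ALPHA_LENGTH_W)
                beta = fresh_cdr3(_BETA_LENGTHS, _BETA_LENGTH_W)
                va, ja = str(rng.choice(_TRAV_POOL)), str(rng.choice(_TRAJ_POOL))
                vb, jb = str(rng.choice(_TRBV_POOL)), str(rng.choice(_TRBJ_POOL))
                if kind == "multi_chain":
                    extra = fresh_cdr3(_BETA_LENGTHS, _BETA_LENGTH_W)
                    rows = [("TRA", alpha, va, ja, "T"), ("TRB", beta, vb, jb, "T"),
                            ("TRB", extra, str(rng.choice(_TRBV_POOL)), jb, "T")]
                elif kind == "orphan":
                    rows = ([("TRA", alpha, va, ja, "T")]
                            if rng.random() < 0.5 else [("TRB", beta, vb, jb, "T")])
                elif kind == "nonproductive_only":
                    rows = [("TRA", alpha[:5] + "*" + alpha[5:], va, ja, "F"),
                            ("TRB", beta[:5] + "*" + beta[5:], vb, jb, "F")]
                else:  # invariant MAIT-like receptor
                    rows = [("TRA", alpha, "TRAV1-2", "TRAJ33", "T"),
                            ("TRB", beta, vb, jb, "T")]
                for locus, cdr3, v, j, prod in rows:
                    chain_rows.append({
                        "cell_id": cell_id, "locus": locus, "junction_aa": cdr3,
                        "junction": "", "v_call": v, "j_call": j,
                        "productive": prod, "duplicate_count": int(rng.integers(1, 20)),
                    })
    if chain_rows:
        chains = pd.concat([chains, pd.DataFrame(chain_rows)], ignore_index=True)
        meta = pd.concat([meta, pd.DataFrame(meta_rows)], ignore_index=True)
    return chains, meta


def _mark_expanded_cells(meta: pd.DataFrame, truth: GroundTruth) -> None:
    """Post-timepoint regulatory cells in clonotypes with >= 2 such cells."""
    sub = meta[(meta["phenotype"] == "Treg") & (meta["timepoint"] == "post")]
    sub = sub[sub["cell_id"].isin(truth.clonotype_of_cell)]
    clono = sub["cell_id"].map(truth.clonotype_of_cell)
    sizes = clono.value_counts()
    expanded = sub.loc[clono.map(sizes).ge(2), "cell_id"]
    truth.expanded_cells = set(expanded)


def simulate_expression(
    meta: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Log-normalized expression for the post-timepoint regulatory cells.

    Counts are Poisson with per-gene log-normal baseline means and
    per-cell log-normal depth factors; planted differentially expressed
    genes are shifted by the configured log2 effect (alternating sign) in
    the expanded cells.  Values are log1p of depth-normalized counts.
    """
    config = config or SimulationConfig()
    expr_cfg = config.expression
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    cells = meta[(meta["phenotype"] == "Treg") & (meta["timepoint"] == "post")]
    cells = cells[cells["cell_id"].isin(truth.clonotype_of_cell)]["cell_id"].tolist()
    if not cells:
        raise ValueError("no post-timepoint regulatory cells to simulate")
    genes = [f"G{i:04d}" for i in range(expr_cfg.n_genes)]
    base = rng.lognormal(expr_cfg.base_mean_log, expr_cfg.base_mean_sigma,
                         size=expr_cfg.n_genes)
    de_idx = rng.choice(expr_cfg.n_genes, size=expr_cfg.n_de_genes, replace=False)
    base[de_idx] = expr_cfg.de_base_mean
    effects = np.zeros(expr_cfg.n_genes)
    signs = np.where(np.arange(expr_cfg.n_de_genes) % 2 == 0, 1.0, -1.0)
    effects[de_idx] = expr_cfg.de_log2fc * signs
    truth.de_effects = {genes[i]: float(effects[i]) for i in de_idx}

    expanded = np.array([c in truth.expanded_cells for c in cells])
    depth = rng.lognormal(0.0, expr_cfg.lib_sigma, size=len(cells))
    lam = np.outer(np.ones(len(cells)), base)
    lam[expanded] = lam[expanded] * np.power(2.0, effects)
    counts = rng.poisson(lam * depth[:, None])
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    log_norm = np.log1p(counts / totals * expr_cfg.target_sum)
    return pd.DataFrame(log_norm, index=cells, columns=genes)


def emit_reference_cdr3_sets(
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_per_family: int = 15,
    n_naive: int = 60,
) -> pd.DataFrame:
    """Labelled reference CDR3 lists for cross-dataset clustering tests.

    ``athero_ref`` sequences share the query's planted motif families (as
    published disease-associated TCR sets would); ``HC_ref`` sequences are
    motif-free naive draws.  Returned as a (cdr3_aa, dataset_label) table.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for family in config.motif_families:
        for seq in motif_family_cdr3s(family.motif, n_per_family, rng):
            rows.append({"cdr3_aa": seq, "dataset_label": "athero_ref"})
    for seq in naive_cdr3_set(n_naive, rng):
        rows.append({"cdr3_aa": seq, "dataset_label": "athero_ref"})
    for seq in naive_cdr3_set(n_naive + 2 * n_per_family, rng):
        rows.append({"cdr3_aa": seq, "dataset_label": "HC_ref"})
    return pd.DataFrame(rows)


def write_study(chains: pd.DataFrame, meta: pd.DataFrame, out_dir) -> None:
    """Write the simulated study as AIRR TSV + metadata TSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chains.to_csv(out / "chains.airr.tsv", sep="\t", index=False)
    meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)
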