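# clonotrack

Longitudinal single-cell TCR repertoire analysis for paired
scTCR-seq/scRNA-seq trial data, built around the question: *which T-cell
clones does a treatment expand, and what happens to their phenotype over
time?* The motivating setting is low-dose interleukin-2 (IL-2) therapy
after acute coronary syndrome, where IL-2 preferentially expands
regulatory T (Treg) cells via the high-affinity trimeric IL-2 receptor,
but the toolkit applies to any placebo-controlled, two-timepoint design
with per-cell receptor sequences and phenotype labels.

## What it computes

- **Clonotype definition by alignment distance.** Cells with a single
  productive αβ chain pair are clustered on both CDR3 arms with the
  distance `d(a,b) = min(S(a,a), S(b,b)) − S(a,b)`, where `S` is the
  optimal global alignment score under BLOSUM62 with affine gaps (gap of
  length L costs 11 + L). Two receptors are clonally related when both
  α and β distances are ≤ 10 (configurable); clonotypes are connected
  components. V-gene matching is not enforced.
- **Clonal expansion and diversity.** Clonotype-size spectra and bins
  (1 / 2–5 / 6–10 / 11–20 / 21+), Shannon entropy `H = −Σ pᵢ log₂ pᵢ`,
  and D50 (minimal number of top clonotypes covering half the cells),
  with chi-squared comparisons between arms.
- **TCR tracking.** Using the clonotype as a barcode (never claiming
  same-cell identity), clones present at both timepoints of a patient
  are matched; per-arm shared-cell fractions are tested by chi-squared,
  pre/post phenotype-transition tables by the exact r×c Fisher test
  (probability-mass ordering, full enumeration), and an empirical
  row-stochastic phenotype transition matrix is estimated from all
  cross-timepoint cell pairs of shared clonotypes.
- **Specificity-group (motif) clustering.** GLIPH-style clustering of
  CDR3β: global edges join equal-length sequences differing at one
  exchangeable position (BLOSUM62 score ≥ 1); local edges join sequences
  sharing a background-enriched 3/4-mer whose position varies by ≤ 3;
  cross-dataset fractions quantify co-clustering with labelled reference
  repertoires; position-frequency matrices feed sequence logos.
- **Expansion phenotype.** Cells of a subset are labelled expanded when
  their clonotype has ≥ 2 members within the subset; per-gene two-sided
  Wilcoxon differential expression with Benjamini–Hochberg correction
  (significant: q < 0.05 and |log₂FC| > 0.3), signal-to-noise-ranked
  GSEA with permutation NES, and signature scores.
- **Synthetic cohorts.** A generator emulating the trial design
  (placebo n=4, 1.5 MIU n=6, 2.5 MIU n=6 patients; two timepoints;
  geometric clone-size law; arm-dependent Treg proportions, clonotype
  persistence, transition kernels; planted motif families, DE genes and
  QC defects) with complete ground truth, so every stage is tested as a
  parameter-recovery problem.

## Worked example

```python
import clonotrack as ct
from clonotrack.alignment import AlignmentParams
from clonotrack.io import chains_from_frame, meta_from_frame, qc_single_paired
from clonotrack.simulate import SimulationConfig, simulate_study

chains, meta, truth = simulate_study(SimulationConfig(seed=1, cells_per_sample=300))
cells, report = qc_single_paired(chains_from_frame(chains), meta_from_frame(meta))
print(f"{report.n_single_paired}/{report.n_input_cells} single-paired "
      f"({100 * report.fractions['single_paired']:.0f}%)")

assignment = ct.define_clonotype_clusters(cells, AlignmentParams(cutoff=10))
shared = ct.match_clonotypes(assignment, meta_from_frame(meta))
for arm, s in shared.items():
    print(arm, f"shared clonotypes: {s.n_shared_clonotypes},",
          f"shared cells: {100 * s.shared_cell_fraction:.2f}%")

p = ct.fisher_exact_rxc(ct.ContingencyTable([[6, 1, 0], [1, 3, 2]]))
print(f"tracked-phenotype shift, exact Fisher p = {p:.4f}")
```

prints

```
9600/10432 single-paired (92%)
placebo shared clonotypes: 16, shared cells: 2.04%
IL2_1.5 shared clonotypes: 19, shared cells: 5.03%
IL2_2.5 shared clonotypes: 14, shared cells: 4.56%
tracked-phenotype shift, exact Fisher p = 0.0414
```

The Fisher example is the 2×3 pre/post table of tracked clonotypes
touching the Treg compartment (6 Treg + 1 Tcm cells before, 1 Treg +
3 Tcm + 2 Tem after): the exact test quantifies the contraction of the
regulatory compartment. The shared-cell fractions show the
IL-2-treated arms carrying more clonally persistent cells than placebo
(at this reduced sample size; the trial-scale defaults are tighter).

## Layout

```
src/clonotrack/
  stats.py        exact r×c Fisher, chi-squared, t, Wilcoxon, BH
  alignment.py    numba Gotoh global aligner + BLOSUM62 distance
  io.py           AIRR / 10x chain tables, metadata, QC funnel
  clonotyping.py  distance clustering, size spectra, clonotype network
  diversity.py    Shannon, D50, size bins, arm comparisons
  tracking.py     shared clonotypes, transition tables/matrices, Sankey
  motifs.py       GLIPH-style local/global clustering, PFMs
  expression.py   expanded-vs-non DE, GSEA, signature scores
  simulate.py     ground-truthed synthetic cohort generator
  cli.py          `clonotrack` command-line entry points
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
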