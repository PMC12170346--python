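# Methods

This note documents the models, conventions and numerical choices behind
`clonotrack`, what the synthetic cohort generator does and does not
emulate, and the known limitations.

## Receptor QC

A cell enters analysis only with exactly one productive TRA and one
productive TRB chain. Cells with ≥ 2 productive chains of the same locus
are `multi_chain`; cells whose productive chains cover one locus only are
`orphan`; cells with no productive chain are `nonproductive_only`.
Additional *non-productive* chains beside a clean pair are ignored — the
ambiguity in practice concerns multiple productive chains, and discarding
a cell for a non-productive background contig would throw away valid
pairs. Invariant receptors are removed after pairing; the default rule
list (MAIT: TRAV1-2 with TRAJ33/TRAJ20/TRAJ12; iNKT: TRAV10 with TRAJ18)
is a stated convention and fully configurable, since which invariant
combinations a given study removes is a lab-specific choice. Cell
barcodes are treated as sample-scoped; an optional `scope_barcodes` flag
prefixes `patient_timepoint` to guarantee global uniqueness (off by
default because the bundled generator already emits unique ids).

## Clonotype distance

The distance between two CDR3 amino-acid sequences is

    d(a, b) = min(S(a,a), S(b,b)) − S(a,b)

with `S` the optimal *global* alignment score under BLOSUM62 and affine
gap costs: a gap of length L costs `gap_open + gap_extend·L` (defaults
11 + L, the protein-search convention; the gap scheme is a package
choice). This convention makes `d(a,a) = 0`, `d` symmetric and
non-negative, so an integer cutoff (default 10) is directly
interpretable in score units. "Both receptor arms" is read strictly:
two receptors are related iff *both* the α and the β distance are within
the cutoff (`arms="all"`); `"any"` (OR) and `"combined"`
(d_α + d_β ≤ cutoff) are available. Clonotypes are connected components
of the relatedness graph over unique (α, β) CDR3 pairs, mapped back to
cells; transitive merging can therefore join receptors individually
farther apart than the cutoff, which is inherent to the component
formulation and accepted.

The scoring kernel is a numba-compiled Gotoh dynamic program verified in
the test suite against biotite's affine-gap global aligner under the
identical cost model. The all-pairs search prunes a pair without running
the DP when its distance provably exceeds the cutoff: for
diagonal-dominant matrices (every BLOSUM62 diagonal entry is a row
maximum, asserted at run time), any cross score obeys
`S(a,b) ≤ S_short − gap_open − gap_extend·Δlen` for unequal lengths, so
`d ≥ min(S_aa, S_bb) − S_short + gap_open + gap_extend·Δlen`. With the
default penalties this removes nearly all unequal-length comparisons
losslessly. At `cutoff=0` clustering reduces to exact (α, β) identity
and is computed by hashing.

Clonotype ids are deterministic (descending size, then lexicographically
smallest member β CDR3). The clonotype *network* reports clonotypes of
size ≥ 15; because two distinct components can never be within the
clustering cutoff on both arms (they would have merged), "closely
related" network edges use a wider margin — twice the cutoff by default,
configurable.

## Diversity and expansion

Shannon entropy is reported in bits (base 2; the base is a package
convention) with a normalized variant H/log₂R (0 when R = 1). D50 uses
the ≥ 50% convention with a stable descending sort. Size bins are
1 / 2–5 / 6–10 / 11–20 / 21+, with proportions counted over clonotypes
by default (a cell-weighted basis is exposed; figure-style legends are
ambiguous between the two). Between-arm bin comparisons use Pearson's
chi-squared without continuity correction on the raw count table; bins
empty in both groups are pooled away. The published degrees of freedom
for the corresponding comparisons (59 and 69) cannot arise from a 2×5
table and the construction behind them is not stated; the package
implements the standard (r−1)(c−1) convention and does not attempt to
reverse-engineer the printed values.

## Exact Fisher test (r×c)

The exact conditional test enumerates every non-negative integer table
with the observed margins (depth-first, last row and column forced by
the margins); a table has probability `(Π rᵢ!)(Π cⱼ!)/(N! Π nᵢⱼ!)`. The
two-sided p-value uses probability-mass ordering — the sum of
probabilities of all tables no more probable than the observed one —
with a relative tie tolerance of 1e-9, matching the standard
exact-network convention. The enumeration asserts that table
probabilities sum to 1 (tolerance 1e-7) on every call; 2×2 results equal
the hypergeometric closed form. A grand-total guard (500 by default)
rejects tables whose enumeration would be intractable, with an explicit
pointer toward Monte Carlo approximation (not implemented).

## TCR tracking

A clonotype is shared for a patient iff it has ≥ 1 member cell at both
timepoints; sharing never claims same-cell identity, only clonal
relatedness. Shared-cell fractions per arm are compared by chi-squared
on 2×2 (shared vs non-shared × arm) tables plus a global r×2 test.
Transition tables count tracked pre-cells (row 1) and post-cells
(row 2) by phenotype, collapsed to a CD4 scheme
{Treg, naive, Tcm, Tem} by default (CD8 labels dropped, mapping
configurable); the restriction "clonotypes touching the Treg
compartment" keeps clonotypes with ≥ 1 Treg cell at either timepoint.
Significance uses the exact Fisher test after dropping all-zero columns;
an empty or single-column table returns p = 1.

The empirical transition matrix replaces trajectory-kernel flow
analysis with a direct estimator: every (pre-cell, post-cell) pair
within a shared clonotype contributes one phenotype transition, weighted
1/(n_pre·n_post) so each clonotype contributes total weight 1
(per-clonotype weighting; matrix invariant to duplicating a clonotype's
cells) or weight 1 (per-pair). Rows are normalized to sum to 1; source
phenotypes never observed at pre are reported as undefined (NaN), never
zero-filled. Outgoing flow from phenotype i is 1 − M[i,i].

## Motif (specificity-group) clustering

Nodes are unique CDR3β amino-acid sequences. Global edges join
equal-length sequences differing at exactly one position whose
substituted residue pair has BLOSUM62 score ≥ 1 ("exchangeable";
the strictly-positive threshold is a package choice — published
descriptions name the matrix but not a cutoff). Local edges require a
shared k-mer (k ∈ {3,4}) mined from flank-trimmed interiors (3 residues
each side, the GLIPH convention) that is enriched over a naive
background: per unique CDR3 presence/absence, one-sided hypergeometric
p ≤ 1e-3, fold ≥ 10, query count ≥ 3, and motif start positions within
3 of each other in trimmed coordinates. Sequences shorter than 8
residues are excluded from mining (logged) but still participate in
global edges. Clusters are connected components of the union graph,
reported at a minimum size (3 by default; 10 and 20 match common
reporting thresholds). The cross-dataset fraction is computed over
unique CDR3s (not cells): among clustered query-label sequences, the
fraction whose cluster contains ≥ 1 reference-label sequence.

The default background is generated by the simulator's naive-repertoire
CDR3 model (position-independent residue frequencies, lengths 11–19,
C...F framing) rather than shipped as data; any user-supplied list can
replace it. Clone-size weighting is off by default (motif statistics
count CDR3 instances), with entry weights available.

## Differential expression, GSEA, signatures

Expanded = clonotype size ≥ 2 *within* the chosen subset and timepoint
(post-treatment regulatory cells by default). DE runs per-gene two-sided
Wilcoxon rank-sum tests (normal approximation with tie and continuity
corrections — the dataset-scale branch of the rank-sum implementation)
with Benjamini–Hochberg correction over all tested genes jointly; genes
expressed in < 3 cells are excluded first (threshold logged). log₂FC
uses the expm1-mean convention of single-cell toolchains,
`log2((mean(expm1 x₁)+ε)/(mean(expm1 x₂)+ε))` with ε = 1e-9;
significance requires q < 0.05 and |log₂FC| > 0.3.

GSEA ranks genes by signal-to-noise `(μ₁−μ₂)/(σ₁+σ₂)` with each σ
floored at 0.2·|μ| (0.2 when μ = 0, the Broad convention); the
enrichment score is the maximum deviation of the running sum weighted by
|metric|¹. NES divides ES by the mean same-sign permutation ES; p is the
same-sign permutation tail with a +1 correction and q its BH adjustment
across sets. Phenotype (label) permutation is used when both groups have
≥ 15 cells; below that it falls back to gene-set permutation, where
label permutation is unstable. Signature scores are per-cell means of
across-cell z-scored expression; zero-variance and missing genes are
excluded and logged.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not the biology of V(D)J recombination:

- **Design**: 3 arms (placebo 4, 1.5 MIU 6, 2.5 MIU 6 patients), two
  timepoints, 2500 QC-clean cells per sample by default.
- **Clone sizes**: geometric with p = 0.7 truncated at 1000 — most
  clonotypes unique, a long tail of expanded clones.
- **Phenotypes**: 8 labels. A clonotype carries a base phenotype; each
  cell reports it with 5% uniform label noise. Observed regulatory
  fractions are targeted exactly in expectation by inverting the noise
  (pre 2% everywhere; post 4 / 6 / 9% by arm). The noise default is a
  package choice pitched at the error rate of automated label transfer;
  with rare phenotypes, much larger noise rates would make
  observed-label conditioning dominated by mislabelled cells.
- **Persistence**: a clonotype persists to the post timepoint with
  probability ρ·mult(phenotype), with regulatory clones 3× as persistent
  (cytokine- and antigen-engaged clones are preferentially retained).
  Persisting clones re-draw sizes inflated by an arm "boost" (placebo 1,
  IL-2 arms 6), producing persistence-driven expansion and the lower
  post-treatment entropy of treated arms. ρ is calibrated analytically
  from the arm's shared-cell-fraction target (1.5 / 7.1 / 3.5%):
  `ρ = 2·target / ((1+boost)·E[mult])`; `scripts/calibrate_persistence.py`
  re-verifies the calibration by simulation.
- **Transitions**: persisting clones evolve their base phenotype by an
  arm kernel. The placebo kernel contracts the regulatory compartment
  toward memory/effector phenotypes (Treg self-retention 0.15, mirroring
  the post-infarct inflammatory skew); the IL-2 kernel retains it
  (0.80). CD4 and CD8 blocks do not mix.
- **Sequences**: CDR3s are C...F-framed strings with interiors drawn
  from a fixed amino-acid frequency table, lengths 10–19; V/J genes from
  rank-weighted pools. Motif families rewrite the β CDR3 of selected
  expanded regulatory clones to carry a planted 4-mer at a ≤ 3-jittered
  interior position.
- **QC defects**: extra cells with multiple productive chains (0.6%),
  orphan chains (5%), non-productive-only chains (2%) and MAIT-like
  invariant receptors (0.4%) are appended at deterministic per-input
  rates and recorded in the truth object.
- **Expression**: Poisson counts with log-normal per-gene baselines and
  per-cell depths, log1p-normalized; planted DE genes (default 20,
  |log₂FC| = 1, alternating sign, marker-level baseline mean 5) are
  shifted in expanded regulatory cells.

What it does *not* emulate — and hence what passing recovery tests do
not show about real data: V(D)J generative sequence statistics and
germline convergence, HLA structure, batch effects, UMI noise, doublets,
cross-reactive receptors, or expression realism beyond what the DE/GSEA
stages require. Planted clonotypes have essentially disjoint CDR3s, so
exact-identity clustering and alignment-distance clustering coincide on
generator output; the alignment path is validated separately by
brute-force oracle equivalence, and cohort-scale recovery runs use the
exact-identity limit for tractability.

## Problem sizes used in tests

The test suite runs the full pipeline on cohorts of 300 cells/sample
(session fixture) and on 20 replicate cohorts at the design size of
2500 cells/sample for the qualitative arm-ordering checks (placebo
higher post entropy and higher Treg outgoing flow than both IL-2 arms).
Kernel recovery uses a dedicated noise-free configuration with raised
persistence (~6,000 tracked clonotypes) so the ±0.05 sup-norm band is
several standard errors wide; DE recovery uses the trial-scale group sizes
(127 expanded vs 1103 non-expanded cells). Because the planted
log₂-fold-change band of ±0.2 is a ≈2σ interval at those group sizes,
the recovery check requires ≥ 90% of planted genes inside the band with
unbiased mean error, rather than every gene.

## Known limitations

- The exact Fisher enumeration is practical only for small tables
  (tracking-scale counts); no Monte Carlo fallback is provided.
- Transitive clonotype merging can chain distinct specificities through
  intermediate sequences in very dense repertoires.
- The empirical transition matrix conditions on observed phenotypes;
  with label noise and rare source phenotypes the matrix mixes rows in
  proportion to the mislabelling odds, which is why estimator validation
  is run noise-free and study-level claims are kept qualitative.
- GSEA's FDR differs from the original two-level normalization scheme:
  q is a BH adjustment of per-set permutation p-values, a simpler and
  more conservative construction.
- The motif stage does not reproduce full GLIPH2 scoring (V-gene bias,
  HLA, cluster significance); published cluster counts are therefore
  not comparable targets.
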