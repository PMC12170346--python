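import numpy as np
import pytest

from clonotrack.alignment import AA_ALPHABET, AlignmentParams, receptor_distance
from clonotrack.clonotyping import (
    clonotype_size_spectrum,
    define_clonotype_clusters,
    export_clonotype_network,
)
from clonotrack.io import CellMeta, CellReceptor, ChainRecord


def make_cell(cell_id, alpha, beta, phenotype="CD4_Tcm", patient="P00"):
    return CellReceptor(
        cell_id,
        ChainRecord(cell_id, "TRA", alpha, "TRAV3", "TRAJ2", True),
        ChainRecord(cell_id, "TRB", beta, "TRBV2", "TRBJ1-1", True),
        CellMeta(cell_id, patient, "pre", "placebo", phenotype),
    )


def random_receptors(rng, n, mutate_fraction=0.4):
    """Random paired CDR3s plus single-residue variants of earlier ones,
    so fixtures contain both singletons and within-cutoff neighbours."""
    alphabet = list(AA_ALPHABET)

    def seq(lo=9, hi=15):
        return "".join(rng.choice(alphabet, size=rng.integers(lo, hi)))

    pairs = [(seq(), seq()) for _ in range(n)]
    for i in range(int(n * mutate_fraction)):
        a, b = pairs[rng.integers(0, n)]
        which = rng.integers(0, 2)
        s = list(a if which == 0 else b)
        pos = rng.integers(0, len(s))
        s[pos] = alphabet[rng.integers(0, 20)]
        mutated = "".join(s)
        pairs.append((mutated, b) if which == 0 else (a, mutated))
    return [make_cell(f"c{i:03d}", a, b) for i, (a, b) in enumerate(pairs)]


def bruteforce_partition(cells, params, arms="all"):
    """All-pairs receptor distances + union-find, the oracle partition."""
    keys = sorted({(c.alpha.cdr3_aa, c.beta.cdr3_aa) for c in cells})
    parent = list(range(len(keys)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            da = receptor_distance(keys[i][0], keys[j][0], params)
            db = receptor_distance(keys[i][1], keys[j][1], params)
            if arms == "all":
                ok = da <= params.cutoff and db <= params.cutoff
            elif arms == "any":
                ok = da <= params.cutoff or db <= params.cutoff
            else:
                ok = da + db <= params.cutoff
            if ok:
                parent[find(i)] = find(j)
    key_of = {c.cell_id: (c.alpha.cdr3_aa, c.beta.cdr3_aa) for c in cells}
    index = {k: i for i, k in enumerate(keys)}
    groups = {}
    for c in cells:
        groups.setdefault(find(index[key_of[c.cell_id]]), set()).add(c.cell_id)
    return {frozenset(g) for g in groups.values()}


class TestDefineClonotypeClusters:
    def test_identical_receptors_form_one_clonotype(self):
        cells = [make_cell(f"c{i}", "CAVRDNF", "CASSLGETQYF") for i in range(5)]
        assignment = define_clonotype_clusters(cells)
        assert len(assignment.members) == 1
        assert assignment.sizes[next(iter(assignment.members))] == 5

    def test_cutoff_zero_is_exact_identity(self):
        rng = np.random.default_rng(0)
        cells = random_receptors(rng, 30)
        assignment = define_clonotype_clusters(cells, AlignmentParams(cutoff=0))
        expected = {}
        for c in cells:
            expected.setdefault((c.alpha.cdr3_aa, c.beta.cdr3_aa), set()).add(c.cell_id)
        assert {frozenset(v) for v in expected.values()} == {
            frozenset(m) for m in assignment.members.values()
        }

    @pytest.mark.parametrize("arms", ["all", "any", "combined"])
    def test_matches_bruteforce_oracle(self, arms):
        params = AlignmentParams(cutoff=10)
        for seed in range(4):
            rng = np.random.default_rng(seed)
            cells = random_receptors(rng, 20)
            assignment = define_clonotype_clusters(cells, params, arms=arms)
            assert {frozenset(m) for m in assignment.members.values()} == (
                bruteforce_partition(cells, params, arms)
            )

    def test_partition_property(self, assignment, cells):
        assert sum(assignment.sizes.values()) == len(cells)
        assert set(assignment.cell_to_clonotype) == {c.cell_id for c in cells}

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(9)
        cells = random_receptors(rng, 25)
        n_by_cutoff = [
            len(define_clonotype_clusters(cells, AlignmentParams(cutoff=c)).members)
            for c in (0, 5, 10, 20)
        ]
        assert all(a >= b for a, b in zip(n_by_cutoff, n_by_cutoff[1:]))

    def test_deterministic_ids(self):
        rng = np.random.default_rng(5)
        cells = random_receptors(rng, 20)
        a = define_clonotype_clusters(cells).as_frame()
        b = define_clonotype_clusters(list(reversed(cells))).as_frame()
        assert a.equals(b)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            define_clonotype_clusters([])


class TestSizeSpectrum:
    def test_singletons(self, ):
        cells = [make_cell(f"c{i}", f"CAVRDN{aa}F", f"CASSLG{aa}F")
                 for i, aa in enumerate("GHIKM")]
        assignment = define_clonotype_clusters(cells, AlignmentParams(cutoff=0))
        spec = clonotype_size_spectrum(assignment, [c.meta for c in cells])
        assert spec.set_index("clonotype_size")["n_clonotypes"].to_dict() == {1: 5}

    def test_cell_conservation(self, assignment, meta_records):
        spec = clonotype_size_spectrum(assignment, meta_records, "all")
        assert (spec["clonotype_size"] * spec["n_clonotypes"]).sum() == (
            sum(len(m) for m in assignment.members.values())
        )

    def test_compartment_split(self, assignment, meta_records):
        full = clonotype_size_spectrum(assignment, meta_records, "all")
        cd4 = clonotype_size_spectrum(assignment, meta_records, "CD4")
        cd8 = clonotype_size_spectrum(assignment, meta_records, "CD8")
        n_cells = (full["clonotype_size"] * full["n_clonotypes"]).sum()
        n_cd4 = (cd4["clonotype_size"] * cd4["n_clonotypes"]).sum()
        n_cd8 = (cd8["clonotype_size"] * cd8["n_clonotypes"]).sum()
        assert n_cd4 + n_cd8 == n_cells

    def test_unknown_compartment(self, assignment, meta_records):
        with pytest.raises(ValueError):
            clonotype_size_spectrum(assignment, meta_records, "NK")

    def test_geometric_tail_shape(self, study, assignment):
        """Pre-timepoint clonotype sizes follow the planted geometric law
        (chi-squared goodness of fit on pooled bins, p > 0.01)."""
        from scipy.stats import chisquare

        config, _, meta, _ = study
        pre_cells = set(meta.loc[meta["timepoint"] == "pre", "cell_id"])
        sizes: dict[str, int] = {}
        for cell, cid in assignment.cell_to_clonotype.items():
            if cell in pre_cells:
                sizes[cid] = sizes.get(cid, 0) + 1
        counts = np.bincount(list(sizes.values()), minlength=4)[1:]
        obs = np.array([counts[0], counts[1], counts[2:].sum()])
        p = config.clone_geom_p
        probs = np.array([p, (1 - p) * p, (1 - p) ** 2])
        exp = probs / probs.sum() * obs.sum()
        _, pval = chisquare(obs, exp)
        assert pval > 0.01


class TestClonotypeNetwork:
    def test_all_singletons_empty_graph(self):
        cells = [make_cell(f"c{i}", f"CAVRDN{aa}F", f"CASSLG{aa}F")
                 for i, aa in enumerate("GHIKM")]
        assignment = define_clonotype_clusters(cells, AlignmentParams(cutoff=0))
        graph = export_clonotype_network(assignment, min_size=15)
        assert graph.number_of_nodes() == 0

    def test_single_large_clonotype(self):
        cells = [make_cell(f"c{i}", "CAVRDNF", "CASSLGETQYF") for i in range(20)]
        assignment = define_clonotype_clusters(cells)
        graph = export_clonotype_network(assignment, min_size=15)
        assert graph.number_of_nodes() == 1
        node = next(iter(graph.nodes(data=True)))
        assert node[1]["size"] == 20 and node[1]["private"]

    def test_related_clonotypes_linked(self):
        # beta CDR3s differ by one Y->F substitution: distance 4, beyond the
        # clonotype cutoff 2 but within the relatedness margin 2 * cutoff
        cells = [make_cell(f"a{i}", "CAVRDNF", "CASSLGETQYF") for i in range(16)]
        cells += [make_cell(f"b{i}", "CAVRDNF", "CASSLGETQFF", patient="P01")
                  for i in range(16)]
        params = AlignmentParams(cutoff=2)
        assignment = define_clonotype_clusters(cells, params)
        assert len(assignment.members) == 2
        graph = export_clonotype_network(assignment, params, min_size=15)
        assert graph.number_of_nodes() == 2 and graph.number_of_edges() == 1
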