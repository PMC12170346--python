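import numpy as np
import pandas as pd
import pytest

from clonotrack.clonotyping import ClonotypeAssignment
from clonotrack.expression import (
    differential_expression,
    gsea_signal_to_noise,
    label_expanded,
    read_expression_mtx,
    signature_score,
    signature_summary,
    write_expression_mtx,
)
from clonotrack.io import CellMeta
from clonotrack.simulate import (
    ExpressionConfig,
    GroundTruth,
    SimulationConfig,
    simulate_expression,
)
from clonotrack.stats import wilcoxon_rank_sum


def make_assignment(mapping):
    assignment = ClonotypeAssignment({}, {}, {})
    for cell, cid in mapping.items():
        assignment.cell_to_clonotype[cell] = cid
        assignment.members.setdefault(cid, []).append(cell)
    return assignment


def trial_expression(seed=0, n_exp=127, n_non=1103, expr_config=None):
    """Expression for the trial's group sizes (127 expanded vs 1103
    non-expanded regulatory cells), with planted effects in the truth."""
    cells = [f"c{i:04d}" for i in range(n_exp + n_non)]
    meta = pd.DataFrame({
        "cell_id": cells, "patient_id": "P00", "timepoint": "post",
        "arm": "IL2_1.5", "phenotype": "Treg",
    })
    truth = GroundTruth(
        clonotype_of_cell={c: "ct0" for c in cells},
        expanded_cells=set(cells[:n_exp]),
    )
    config = SimulationConfig(seed=seed, expression=expr_config or ExpressionConfig())
    expr = simulate_expression(meta, truth, config, seed=seed)
    labels = pd.Series(
        ["expanded"] * n_exp + ["non_expanded"] * n_non, index=cells, name="expansion"
    )
    return expr, labels, truth


class TestLabelExpanded:
    def _meta(self, rows):
        return [CellMeta(*r) for r in rows]

    def test_pair_is_expanded_singleton_is_not(self):
        assignment = make_assignment({"a": "ct0", "b": "ct0", "c": "ct1"})
        meta = self._meta([
            ("a", "P0", "post", "placebo", "Treg"),
            ("b", "P0", "post", "placebo", "Treg"),
            ("c", "P0", "post", "placebo", "Treg"),
        ])
        labels = label_expanded(assignment, meta)
        assert labels["a"] == labels["b"] == "expanded"
        assert labels["c"] == "non_expanded"

    def test_size_counted_within_subset(self):
        # the clonotype has 2 cells, but only one is a post-timepoint Treg
        assignment = make_assignment({"a": "ct0", "b": "ct0"})
        meta = self._meta([
            ("a", "P0", "post", "placebo", "Treg"),
            ("b", "P0", "pre", "placebo", "Treg"),
        ])
        labels = label_expanded(assignment, meta)
        assert labels["a"] == "non_expanded"

    def test_empty_subset_raises(self):
        assignment = make_assignment({"a": "ct0"})
        meta = self._meta([("a", "P0", "post", "placebo", "CD4_Tem")])
        with pytest.raises(ValueError):
            label_expanded(assignment, meta)

    def test_planted_expanded_cells_recovered(self, study, assignment, meta_records):
        _, _, _, truth = study
        labels = label_expanded(assignment, meta_records)
        expanded = set(labels[labels == "expanded"].index)
        # truth marks expansion on true clonotype ids; alignment clustering
        # reproduces the same partition for the planted receptors
        assert expanded == truth.expanded_cells


class TestDifferentialExpression:
    def test_planted_effects_recovered(self):
        expr, labels, truth = trial_expression(seed=0)
        de = differential_expression(expr, labels).set_index("gene")
        errors = []
        for gene, lfc in truth.de_effects.items():
            est = de.loc[gene, "log2fc"]
            assert de.loc[gene, "significant"]
            assert np.sign(est) == np.sign(lfc)
            errors.append(abs(est - lfc))
        errors = np.array(errors)
        assert errors.mean() <= 0.1
        assert (errors <= 0.2).mean() >= 0.9

    def test_null_labels_give_no_signal(self):
        expr, labels, _ = trial_expression(seed=1)
        rng = np.random.default_rng(0)
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index, name="expansion"
        )
        de = differential_expression(expr, permuted)
        assert de["significant"].sum() <= 1
        assert de["log2fc"].abs().median() < 0.25

    def test_log2fc_antisymmetry(self):
        expr, labels, _ = trial_expression(seed=2, n_exp=50, n_non=50)
        swapped = labels.map({"expanded": "non_expanded", "non_expanded": "expanded"})
        a = differential_expression(expr, labels).set_index("gene")["log2fc"]
        b = differential_expression(expr, swapped).set_index("gene")["log2fc"]
        assert np.allclose(a, -b.loc[a.index])

    def test_agrees_with_scalar_wilcoxon(self):
        expr, labels, _ = trial_expression(seed=3, n_exp=30, n_non=40)
        de = differential_expression(expr, labels).set_index("gene")
        x1 = expr.loc[labels == "expanded"]
        x2 = expr.loc[labels == "non_expanded"]
        for gene in list(de.index[:5]):
            ref = wilcoxon_rank_sum(x1[gene], x2[gene], mode="normal")
            assert de.loc[gene, "p"] == pytest.approx(ref.p, rel=1e-9)

    def test_group_size_guard(self):
        expr, labels, _ = trial_expression(seed=4, n_exp=2, n_non=20)
        with pytest.raises(ValueError):
            differential_expression(expr, labels)


class TestGsea:
    def test_top_ranked_gene_set_concentrates(self):
        expr, labels, _ = trial_expression(seed=5, n_exp=60, n_non=60)
        from clonotrack.expression import _signal_to_noise

        metric = _signal_to_noise(
            expr.loc[labels == "expanded"].to_numpy(),
            expr.loc[labels == "non_expanded"].to_numpy(),
        )
        top = list(expr.columns[np.argsort(-metric)][:20])
        res = gsea_signal_to_noise(
            expr, labels, {"top": top}, n_perm=50, seed=0
        )[0]
        assert res.es > 0.9
        assert set(res.leading_edge) <= set(top)

    def test_seed_determinism(self):
        expr, labels, _ = trial_expression(seed=6, n_exp=40, n_non=40)
        sets = {"s1": list(expr.columns[:10]), "s2": list(expr.columns[50:70])}
        a = gsea_signal_to_noise(expr, labels, sets, n_perm=100, seed=3)
        b = gsea_signal_to_noise(expr, labels, sets, n_perm=100, seed=3)
        assert [(r.gene_set, r.es, r.nes, r.p, r.q) for r in a] == (
            [(r.gene_set, r.es, r.nes, r.p, r.q) for r in b]
        )

    def test_random_sets_have_unit_scale_nes(self):
        expr, labels, _ = trial_expression(seed=7, n_exp=50, n_non=50)
        rng = np.random.default_rng(1)
        sets = {
            f"r{i}": list(rng.choice(expr.columns, size=25, replace=False))
            for i in range(8)
        }
        res = gsea_signal_to_noise(expr, labels, sets, n_perm=100, seed=2)
        med = np.median([abs(r.nes) for r in res])
        assert 0.5 <= med <= 1.5

    def test_small_sets_skipped(self):
        expr, labels, _ = trial_expression(seed=8, n_exp=30, n_non=30)
        res = gsea_signal_to_noise(expr, labels, {"tiny": list(expr.columns[:2])},
                                   n_perm=10, seed=0)
        assert res == []


class TestSignatureScore:
    def test_single_gene_is_zscore(self):
        expr, _, _ = trial_expression(seed=9, n_exp=20, n_non=20)
        gene = expr.columns[0]
        score = signature_score(expr, [gene])
        col = expr[gene]
        z = (col - col.mean()) / col.std(ddof=0)
        assert np.allclose(score, z)

    def test_constant_gene_excluded(self):
        expr, _, _ = trial_expression(seed=10, n_exp=20, n_non=20)
        expr = expr.copy()
        expr["FLAT"] = 1.0
        gene = expr.columns[0]
        score = signature_score(expr, ["FLAT", gene])
        z = (expr[gene] - expr[gene].mean()) / expr[gene].std(ddof=0)
        assert np.allclose(score, z)

    def test_all_missing_raises(self):
        expr, _, _ = trial_expression(seed=11, n_exp=20, n_non=20)
        with pytest.raises(ValueError):
            signature_score(expr, ["NOPE"])

    def test_planted_up_signature_separates_groups(self):
        expr, labels, truth = trial_expression(seed=12)
        up = [g for g, lfc in truth.de_effects.items() if lfc > 0]
        score = signature_score(expr, up)
        assert score[labels == "expanded"].mean() > score[labels == "non_expanded"].mean()
        summary = signature_summary(expr, labels, up)
        assert (summary["log2fc"] > 0).all()


class TestExpressionIO:
    def test_mtx_roundtrip(self, tmp_path):
        expr, _, _ = trial_expression(seed=13, n_exp=10, n_non=10,
                                      expr_config=ExpressionConfig(n_genes=50))
        write_expression_mtx(expr, tmp_path)
        back = read_expression_mtx(tmp_path)
        assert np.allclose(back.to_numpy(), expr.to_numpy())
        assert list(back.columns) == list(expr.columns)
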