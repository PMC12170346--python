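import numpy as np
import pandas as pd
import pytest

from clonotrack.io import CellMeta
from clonotrack.tracking import (
    SharedClonotypeSet,
    build_transition_table,
    empirical_transition_matrix,
    export_sankey,
    match_clonotypes,
    shared_fraction_test,
    transition_significance,
)
from clonotrack.clonotyping import ClonotypeAssignment


def make_assignment(mapping):
    assignment = ClonotypeAssignment({}, {}, {})
    for cell, cid in mapping.items():
        assignment.cell_to_clonotype[cell] = cid
        assignment.members.setdefault(cid, []).append(cell)
    return assignment


def make_meta(rows):
    return [CellMeta(*row) for row in rows]


class TestMatchClonotypes:
    def test_pre_only_not_shared(self):
        assignment = make_assignment({"a": "ct0", "b": "ct1"})
        meta = make_meta([
            ("a", "P0", "pre", "placebo", "Treg"),
            ("b", "P0", "post", "placebo", "Treg"),
        ])
        shared = match_clonotypes(assignment, meta)["placebo"]
        assert shared.n_shared_clonotypes == 0
        assert shared.pre_only == {"ct0"} and shared.post_only == {"ct1"}

    def test_shared_counts_cells_at_both_timepoints(self):
        assignment = make_assignment({c: "ct0" for c in "abcde"})
        meta = make_meta(
            [(c, "P0", "pre", "placebo", "Treg") for c in "ab"]
            + [(c, "P0", "post", "placebo", "CD4_Tem") for c in "cde"]
        )
        shared = match_clonotypes(assignment, meta)["placebo"]
        assert shared.n_shared_clonotypes == 1
        assert shared.n_shared_cells == 5
        assert shared.shared_cell_fraction == 1.0

    def test_patient_missing_timepoint_excluded(self, caplog):
        assignment = make_assignment({"a": "ct0"})
        meta = make_meta([("a", "P0", "pre", "placebo", "Treg")])
        shared = match_clonotypes(assignment, meta)["placebo"]
        assert shared.total_cells == 0

    def test_sharing_symmetric_in_timepoints(self, assignment, meta_records):
        flipped = [
            CellMeta(m.cell_id, m.patient_id,
                     "post" if m.timepoint == "pre" else "pre", m.arm, m.phenotype)
            for m in meta_records
        ]
        fwd = match_clonotypes(assignment, meta_records)
        rev = match_clonotypes(assignment, flipped)
        for arm in fwd:
            assert fwd[arm].shared == rev[arm].shared
            assert fwd[arm].n_shared_cells == rev[arm].n_shared_cells
            assert fwd[arm].pre_only == rev[arm].post_only


class TestSharedFractionTest:
    def test_equal_fractions(self):
        sets = {
            "placebo": SharedClonotypeSet("placebo", n_shared_cells=50, total_cells=1000),
            "IL2": SharedClonotypeSet("IL2", n_shared_cells=100, total_cells=2000),
        }
        res = shared_fraction_test(sets)
        assert res["IL2"].p > 0.99

    def test_matches_pearson_2x2(self):
        sets = {
            "placebo": SharedClonotypeSet("placebo", n_shared_cells=76, total_cells=5000),
            "IL2": SharedClonotypeSet("IL2", n_shared_cells=544, total_cells=7700),
        }
        res = shared_fraction_test(sets)["IL2"]
        table = np.array([[544, 7156], [76, 4924]], dtype=float)
        e = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert res.statistic == pytest.approx(((table - e) ** 2 / e).sum())
        assert res.df == 1

    def test_requires_two_arms(self):
        with pytest.raises(ValueError):
            shared_fraction_test(
                {"placebo": SharedClonotypeSet("placebo", n_shared_cells=1, total_cells=10)}
            )

    def test_planted_arm_effect_detected(self, shared_sets):
        res = shared_fraction_test(shared_sets)
        assert res["IL2_1.5"].p < 0.001
        assert res["global"].p < 0.001


def _tracked_set(tracks, arm="placebo"):
    s = SharedClonotypeSet(arm)
    s.tracks = tracks
    s.shared = {cid for _, cid in tracks}
    return s


class TestTransitionTable:
    def test_reproduces_tracked_phenotype_counts(self):
        """Tracked clonotypes touching the regulatory compartment: 6 Treg +
        1 Tcm cells pre to 1 Treg + 3 Tcm + 2 Tem post, exact p = 0.0414."""
        tracks = {
            ("P0", "ct0"): (["Treg"] * 4 + ["CD4_Tcm"], ["Treg", "CD4_Tcm", "CD4_Tem"]),
            ("P0", "ct1"): (["Treg"] * 2, ["CD4_Tcm"] * 2 + ["CD4_Tem"]),
        }
        table = build_transition_table(_tracked_set(tracks), restrict_to={"Treg"})
        counts = pd.DataFrame(
            table.table.counts, index=table.table.row_labels,
            columns=table.table.col_labels,
        )
        assert counts.loc["pre", ["Treg", "Tcm", "Tem"]].tolist() == [6, 1, 0]
        assert counts.loc["post", ["Treg", "Tcm", "Tem"]].tolist() == [1, 3, 2]
        assert transition_significance(table) == pytest.approx(0.0414, abs=5e-5)

    def test_treg_maintaining_arm_counts(self):
        """High-dose arm: 4 Treg + 3 Tcm + 1 Tem track to 6 Treg + 4 Tcm +
        1 Tem (phenotype retained)."""
        tracks = {
            ("P1", "ct0"): (["Treg"] * 4, ["Treg"] * 6),
            ("P1", "ct1"): (["CD4_Tcm"] * 3 + ["CD4_Tem"], ["CD4_Tcm"] * 4 + ["CD4_Tem"]),
        }
        table = build_transition_table(_tracked_set(tracks, "IL2_2.5"), restrict_to=None)
        counts = pd.DataFrame(
            table.table.counts, index=table.table.row_labels,
            columns=table.table.col_labels,
        )
        assert counts.loc["pre", ["Treg", "Tcm", "Tem"]].tolist() == [4, 3, 1]
        assert counts.loc["post", ["Treg", "Tcm", "Tem"]].tolist() == [6, 4, 1]

    def test_restriction_excludes_non_treg_tracks(self):
        tracks = {("P0", "ct0"): (["CD4_Tcm"], ["CD4_Tem"])}
        table = build_transition_table(_tracked_set(tracks), restrict_to={"Treg"})
        assert table.empty

    def test_empty_tracked_set(self):
        table = build_transition_table(_tracked_set({}))
        assert table.empty
        assert transition_significance(table) == 1.0

    def test_identical_rows_after_zero_column_drop(self):
        tracks = {("P0", "ct0"): (["Treg"] * 3, ["Treg"] * 3)}
        table = build_transition_table(_tracked_set(tracks))
        assert transition_significance(table) == 1.0

    def test_extreme_2x2_matches_hypergeometric(self):
        from scipy.stats import fisher_exact

        tracks = {("P0", "ct0"): (["Treg"] * 5, ["CD4_Tem"] * 5)}
        table = build_transition_table(_tracked_set(tracks))
        p = transition_significance(table)
        _, ref = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(ref)

    def test_transpose_under_timepoint_relabel(self):
        tracks = {("P0", "ct0"): (["Treg", "CD4_Tcm"], ["CD4_Tem"] * 3)}
        fwd = build_transition_table(_tracked_set(tracks), restrict_to=None)
        rev_tracks = {k: (post, pre) for k, (pre, post) in tracks.items()}
        rev = build_transition_table(_tracked_set(rev_tracks), restrict_to=None)
        assert (fwd.table.counts == rev.table.counts[::-1]).all()


class TestTransitionMatrix:
    def test_single_pair(self):
        tracks = {("P0", "ct0"): (["Treg"], ["CD4_Tem"])}
        tm = empirical_transition_matrix(_tracked_set(tracks))
        assert tm.matrix.loc["Treg", "Tem"] == 1.0
        assert tm.outgoing_flow["Treg"] == 1.0

    def test_split_destination(self):
        tracks = {("P0", "ct0"): (["Treg"], ["Treg", "CD4_Tem"])}
        tm = empirical_transition_matrix(_tracked_set(tracks))
        assert tm.matrix.loc["Treg", "Treg"] == pytest.approx(0.5)
        assert tm.matrix.loc["Treg", "Tem"] == pytest.approx(0.5)

    def test_rows_stochastic_and_undefined_flagged(self, shared_sets):
        for arm, shared in shared_sets.items():
            tm = empirical_transition_matrix(shared)
            for label in tm.matrix.index:
                row = tm.matrix.loc[label]
                if label in tm.undefined_rows:
                    assert row.isna().all()
                else:
                    assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_per_clonotype_weighting_duplication_invariant(self):
        tracks = {
            ("P0", "ct0"): (["Treg"], ["Treg", "CD4_Tem"]),
            ("P0", "ct1"): (["CD4_Tcm"] * 2, ["CD4_Tem"]),
        }
        dup = {k: (pre * 3, post * 3) for k, (pre, post) in tracks.items()}
        a = empirical_transition_matrix(_tracked_set(tracks)).matrix
        b = empirical_transition_matrix(_tracked_set(dup)).matrix
        pd.testing.assert_frame_equal(a, b)

    def test_per_pair_weighting_counts_each_pair(self):
        tracks = {("P0", "ct0"): (["Treg"] * 2, ["CD4_Tem"] * 3)}
        tm = empirical_transition_matrix(_tracked_set(tracks), weighting="per-pair")
        assert tm.counts.loc["Treg", "Tem"] == 6.0

    def test_sankey_conserves_flow(self):
        tracks = {
            ("P0", "ct0"): (["Treg"], ["Treg", "CD4_Tem"]),
            ("P0", "ct1"): (["CD4_Tcm"], ["CD4_Tem"]),
        }
        tm = empirical_transition_matrix(_tracked_set(tracks))
        links = export_sankey(tm)
        assert links["weight"].sum() == pytest.approx(tm.counts.to_numpy().sum())
        assert set(links.columns) == {"source", "target", "weight"}

    def test_sankey_empty(self):
        tm = empirical_transition_matrix(_tracked_set({}))
        assert export_sankey(tm).empty
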