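import numpy as np
import pandas as pd
import pytest

from mitoegt import (
    Cladogram,
    GeneStateMatrix,
    TransitionCostMatrix,
    count_transfers_matrix,
    reconstruct_events,
    replacement_events,
    sankoff_min_cost,
)
from mitoegt.parsimony import ParsimonyError, STEM_EDGE
from tests._oracles import brute_force_min, random_topology


class TestSankoffMinCost:
    def test_all_mito_costs_nothing(self, balanced4):
        tips = dict(A="M", B="M", C="M", D="M")
        assert sankoff_min_cost(balanced4, tips) == (0.0, 0, 0)

    def test_all_nuclear_is_one_stem_transfer(self, balanced4):
        tips = dict(A="N", B="N", C="N", D="N")
        c = TransitionCostMatrix(c_t=2.5, c_l=1.0)
        assert sankoff_min_cost(balanced4, tips, c) == (2.5, 1, 0)

    def test_mixed_five_leaf(self, five_leaf):
        tips = dict(A="N", B="N", C="M", D="L", E="N")
        assert sankoff_min_cost(five_leaf, tips) == (3.0, 2, 1)

    def test_unknown_tips_are_free(self, balanced4):
        tips = dict(A="?", B="?", C="?", D="?")
        assert sankoff_min_cost(balanced4, tips) == (0.0, 0, 0)

    def test_dual_counts_as_nuclear(self, balanced4):
        tips = dict(A="D", B="D", C="D", D="D")
        assert sankoff_min_cost(balanced4, tips) == (1.0, 1, 0)

    def test_missing_leaf_assignment_raises(self, balanced4):
        with pytest.raises(ParsimonyError, match="no tip assignment"):
            sankoff_min_cost(balanced4, dict(A="M", B="M", C="M"))

    def test_matches_brute_force_on_random_instances(self, rng):
        """DP equals exhaustive enumeration on 150 random trees/states."""
        states = list("MNLD?")
        for _ in range(150):
            n = int(rng.integers(3, 9))
            tree = Cladogram.from_newick(
                random_topology([f"T{k}" for k in range(n)], rng)
            )
            tips = {l: states[rng.integers(5)] for l in tree.leaf_labels}
            costs = TransitionCostMatrix(
                c_t=float(rng.choice([0.5, 1.0, 2.0])),
                c_l=float(rng.choice([0.5, 1.0, 3.0])),
            )
            assert sankoff_min_cost(tree, tips, costs) == brute_force_min(
                tree, tips, costs
            )

    def test_cost_scaling_leaves_counts_unchanged(self, five_leaf, rng):
        tips = {l: "MNL?"[rng.integers(4)] for l in five_leaf.leaf_labels}
        base = TransitionCostMatrix(1.0, 1.0)
        c0, t0, l0 = sankoff_min_cost(five_leaf, tips, base)
        c3, t3, l3 = sankoff_min_cost(five_leaf, tips, base.scaled(3.0))
        assert (t3, l3) == (t0, l0)
        assert c3 == pytest.approx(3.0 * c0)

    def test_transfers_zero_iff_no_nuclear_tip(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 9))
            tree = Cladogram.from_newick(
                random_topology([f"T{k}" for k in range(n)], rng)
            )
            tips = {l: "MNLD?"[rng.integers(5)] for l in tree.leaf_labels}
            _, transfers, _ = sankoff_min_cost(tree, tips)
            any_nd = any(s in "ND" for s in tips.values())
            if not any_nd:
                assert transfers == 0
            else:
                assert transfers >= 1


class TestReconstructEvents:
    def test_all_mito_empty_event_map(self, balanced4):
        rec = reconstruct_events(balanced4, dict(A="M", B="M", C="M", D="M"))
        assert rec.events == [] and not rec.ambiguous

    def test_all_nuclear_single_stem_transfer(self, balanced4):
        rec = reconstruct_events(balanced4, dict(A="N", B="N", C="N", D="N"))
        assert rec.events == [(STEM_EDGE, "transfer")]
        assert not rec.ambiguous

    def test_mixed_five_leaf_event_placement(self, five_leaf):
        """One transfer covers the (A,B) cherry; E transfers and D loses
        independently (the mito-preferring tie rule keeps their ancestor M)."""
        rec = reconstruct_events(
            five_leaf, dict(A="N", B="N", C="M", D="L", E="N")
        )
        ab_ancestor = five_leaf.leaves()[0].parent_node.edge_id
        assert set(rec.events) == {
            (ab_ancestor, "transfer"),
            ("E", "transfer"),
            ("D", "loss"),
        }
        assert rec.ambiguous  # the (D,E) ancestor ties between M and N
        assert (rec.cost, rec.transfers, rec.losses) == (3.0, 2, 1)

    def test_dual_flag_surfaced(self, balanced4):
        rec = reconstruct_events(balanced4, dict(A="D", B="N", C="M", D="M"))
        assert rec.has_dual

    def test_event_counts_match_dp_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 8))
            tree = Cladogram.from_newick(
                random_topology([f"T{k}" for k in range(n)], rng)
            )
            tips = {l: "MNLD?"[rng.integers(5)] for l in tree.leaf_labels}
            rec = reconstruct_events(tree, tips)
            cost, transfers, losses = sankoff_min_cost(tree, tips)
            assert (rec.cost, rec.transfers, rec.losses) == (
                cost, transfers, losses,
            )


class TestCountTransfersMatrix:
    def test_single_gene_all_mito(self, balanced4):
        m = GeneStateMatrix(
            pd.DataFrame({"g1": ["M"] * 4}, index=list("ABCD"))
        )
        table = count_transfers_matrix(balanced4, m)
        row = table.loc["g1"]
        assert row.transfers == 0 and row.pct_M == 100.0

    def test_percentages_ignore_unknowns(self, balanced4):
        m = GeneStateMatrix(
            pd.DataFrame({"g1": ["M", "N", "?", "D"]}, index=list("ABCD"))
        )
        row = count_transfers_matrix(balanced4, m).loc["g1"]
        assert row.pct_M == pytest.approx(100 / 3)
        assert row.pct_N == pytest.approx(200 / 3)  # D counts as transferred
        assert row.pct_L == 0.0

    def test_taxon_order_invariance(self, balanced4, rng):
        df = pd.DataFrame(
            {"g1": ["M", "N", "L", "N"], "g2": ["M", "M", "D", "?"]},
            index=list("ABCD"),
        )
        t1 = count_transfers_matrix(balanced4, GeneStateMatrix(df))
        perm = df.sample(frac=1.0, random_state=7)
        t2 = count_transfers_matrix(balanced4, GeneStateMatrix(perm))
        pd.testing.assert_frame_equal(t1, t2)

    def test_subset_taxa_prunes_tree(self, five_leaf):
        m = GeneStateMatrix(
            pd.DataFrame({"g1": ["N", "N", "M"]}, index=["A", "B", "C"])
        )
        row = count_transfers_matrix(five_leaf, m).loc["g1"]
        assert row.transfers == 1

    def test_taxon_absent_from_tree_raises(self, balanced4):
        m = GeneStateMatrix(pd.DataFrame({"g1": ["M", "M"]}, index=["A", "Z"]))
        with pytest.raises(Exception, match="absent"):
            count_transfers_matrix(balanced4, m)

    def test_empty_gene_set_raises(self, balanced4):
        m = GeneStateMatrix(pd.DataFrame(index=list("ABCD")))
        with pytest.raises(ParsimonyError, match="empty"):
            count_transfers_matrix(balanced4, m)


class TestReplacementEvents:
    def _matrix(self, rows):
        return GeneStateMatrix(
            pd.DataFrame(rows, columns=["ccmA", "ccmB"], index=list("ABCD"))
        )

    def test_full_retention_zero_events(self, balanced4):
        m = self._matrix([["M", "M"]] * 4)
        count, events = replacement_events(balanced4, m, ["ccmA", "ccmB"])
        assert count == 0 and events == []

    def test_single_taxon_loss(self, balanced4):
        m = self._matrix([["M", "M"], ["M", "M"], ["M", "M"], ["L", "L"]])
        count, events = replacement_events(balanced4, m, ["ccmA", "ccmB"])
        assert count == 1
        assert events == [("D", "loss")]

    def test_two_disjoint_clades_two_events(self):
        tree = Cladogram.from_newick("((A,B),(C,D),(E,F));")
        df = pd.DataFrame(
            {
                "ccmA": ["L", "L", "M", "M", "L", "L"],
                "ccmB": ["L", "L", "M", "M", "L", "L"],
            },
            index=list("ABCDEF"),
        )
        count, events = replacement_events(tree, GeneStateMatrix(df), ["ccmA", "ccmB"])
        assert count == 2

    def test_partial_retention_counts_as_present(self, balanced4):
        # one surviving member keeps the module M
        m = self._matrix([["M", "L"], ["L", "M"], ["D", "L"], ["M", "M"]])
        count, _ = replacement_events(balanced4, m, ["ccmA", "ccmB"])
        assert count == 0

    def test_replacement_marker_scored_as_transfer(self, balanced4):
        m = self._matrix([["M", "M"], ["M", "M"], ["L", "L"], ["L", "L"]])
        marker = {"C": True, "D": True}
        count, events = replacement_events(
            balanced4, m, ["ccmA", "ccmB"], replacement_marker=marker
        )
        assert count == 1  # one replacement on the (C,D) stem
        assert all(ev == "transfer" for _, ev in events)

    def test_gene_absent_raises(self, balanced4):
        m = self._matrix([["M", "M"]] * 4)
        with pytest.raises(Exception, match="absent"):
            replacement_events(balanced4, m, ["ccmZ"])
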