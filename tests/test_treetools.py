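"""NJ reconstruction, Fitch parsimony, searches, bootstrap support."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_additive_tree
from esudelim.errors import EsudelimError
from esudelim.matrices import LabelledMatrix
from esudelim.seqmodels import Alignment, SubstitutionModel
from esudelim.synthetic_data import simulate_alignment
from esudelim.trees import Support, SupportTree
from esudelim.treetools import (bootstrap_support, fitch_length, nj_tree,
                                parsimony_best, supported_bipartitions,
                                splits_conflict)

JC = SubstitutionModel.jc()


def matrix_from(labels, dist):
    n = len(labels)
    vals = np.zeros((n, n))
    for (a, b), d in dist.items():
        i, j = labels.index(a), labels.index(b)
        vals[i, j] = vals[j, i] = d
    return LabelledMatrix(labels, vals)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = matrix_from(["a", "b", "c"],
                         {("a", "b"): 0.3, ("a", "c"): 0.5, ("b", "c"): 0.6})
        tree = nj_tree(dm)
        # three-point formulas: va=(dab+dac-dbc)/2 etc.
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_four_taxon_additive_exact_recovery(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> patristic distances
        dm = matrix_from(list("abcd"),
                         {("a", "b"): 3, ("a", "c"): 8, ("a", "d"): 9,
                          ("b", "c"): 9, ("b", "d"): 10, ("c", "d"): 9})
        tree = nj_tree(dm)
        assert tree.splits() == {frozenset({"c", "d"})}
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 4, "d": 5})

    def test_ultrametric_two_clusters_separated(self):
        labels = ["a1", "a2", "b1", "b2"]
        dist = {}
        for x in labels:
            for y in labels:
                if x < y:
                    same = x[0] == y[0]
                    dist[(x, y)] = 0.02 if same else 0.4
        tree = nj_tree(matrix_from(labels, dist))
        assert frozenset({"b1", "b2"}) in tree.splits()

    def test_missing_entries_rejected(self):
        vals = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2],
                         [np.nan, 0.2, 0]])
        # NaN off-diagonal is rejected at matrix construction already;
        # build via a diagonal-missing matrix to reach the NJ check
        m = LabelledMatrix(["a", "b", "c"],
                           np.array([[np.nan, 0.1, 0.2], [0.1, 0.0, 0.2],
                                     [0.2, 0.2, 0.0]]),
                           "within")
        with pytest.raises(EsudelimError, match="impute or remove"):
            nj_tree(m)
        with pytest.raises(Exception):
            LabelledMatrix(["a", "b", "c"], vals)

    def test_negative_estimates_clamped_with_deficit_moved(self):
        # near-degenerate matrix that produces a negative NJ estimate
        dm = matrix_from(list("abcd"),
                         {("a", "b"): 0.1, ("a", "c"): 0.1, ("a", "d"): 0.4,
                          ("b", "c"): 0.1, ("b", "d"): 0.4, ("c", "d"): 0.3})
        tree = nj_tree(dm)
        for edge in tree.tree.preorder_edge_iter():
            assert (edge.length or 0.0) >= 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_nj_inverts_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        newick, dm = random_additive_tree(rng, n)
        true = SupportTree.from_newick(newick, False)
        assert nj_tree(dm).splits() == true.splits()


class TestFitch:
    def test_textbook_costs(self):
        aln = Alignment(["t1", "t2", "t3", "t4"], ["A", "A", "C", "C"])
        t_same = SupportTree.from_newick("((t1,t2),(t3,t4));", False)
        t_cross = SupportTree.from_newick("((t1,t3),(t2,t4));", False)
        assert fitch_length(aln, t_same) == 1
        assert fitch_length(aln, t_cross) == 2

    def test_constant_site_costs_nothing(self):
        aln = Alignment(["t1", "t2", "t3", "t4"], ["A"] * 4)
        t = SupportTree.from_newick("((t1,t2),(t3,t4));", False)
        assert fitch_length(aln, t) == 0

    def test_gaps_are_zero_cost_wildcards(self):
        aln = Alignment(["t1", "t2", "t3", "t4"], ["A", "-", "C", "N"])
        t = SupportTree.from_newick("((t1,t2),(t3,t4));", False)
        assert fitch_length(aln, t) == 1

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_rerooting(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(5)]
        seqs = ["".join(rng.choice(list("ACGT-N"), 12)) for _ in labels]
        aln = Alignment(labels, seqs)
        t1 = SupportTree.from_newick(
            "((t0,t1),(t2,(t3,t4)));", False)
        t2 = SupportTree.from_newick(
            "(((t2,(t3,t4)),t1),t0);", False)  # same unrooted topology
        assert fitch_length(aln, t1) == fitch_length(aln, t2)


class TestParsimonySearch:
    def test_four_taxa_equals_brute_force_over_three_topologies(self, rng):
        labels = ["t1", "t2", "t3", "t4"]
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in labels]
        aln = Alignment(labels, seqs)
        tops = ["((t1,t2),(t3,t4));", "((t1,t3),(t2,t4));",
                "((t1,t4),(t2,t3));"]
        brute = min(fitch_length(aln, SupportTree.from_newick(t, False))
                    for t in tops)
        _, best = parsimony_best(aln)
        assert best == brute

    def test_perfect_split_signal_recovered(self):
        labels = [f"t{i}" for i in range(6)]
        seqs = ["AAAA" if i < 3 else "CCCC" for i in range(6)]
        aln = Alignment(labels, seqs)
        tree, length = parsimony_best(aln)
        assert length == 4
        assert frozenset({"t3", "t4", "t5"}) in tree.splits() \
            or frozenset({"t1", "t2"}) not in tree.splits()

    def test_constant_alignment_has_zero_length(self):
        aln = Alignment([f"t{i}" for i in range(5)], ["ACGT"] * 5)
        _, length = parsimony_best(aln)
        assert length == 0

    def test_nni_fallback_not_worse_than_nj_start(self, rng):
        labels = [f"t{i}" for i in range(11)]
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in labels]
        aln = Alignment(labels, seqs)
        tree, length = parsimony_best(aln, exhaustive_max=9)
        assert length == fitch_length(aln, tree)

    def test_exhaustive_never_beaten_by_any_fixed_topology(self, rng):
        labels = [f"t{i}" for i in range(6)]
        seqs = ["".join(rng.choice(list("ACGT"), 25)) for _ in labels]
        aln = Alignment(labels, seqs)
        _, best = parsimony_best(aln)
        probe = SupportTree.from_newick(
            "((t0,t5),((t1,t4),(t2,t3)));", False)
        assert best <= fitch_length(aln, probe)


class TestSupportedBipartitions:
    def _tree(self):
        t = SupportTree.from_newick("((a,b),(c,d),(e,f));", False)
        splits = list(t.splits())
        return t, splits

    def test_bs_exactly_70_excluded(self):
        t, splits = self._tree()
        t.supports[splits[0]] = Support(bs=70.0)
        assert len(supported_bipartitions(t)) == 0

    def test_either_type_rule(self):
        t, splits = self._tree()
        t.supports[splits[0]] = Support(bs=65.0, pp=0.99)
        bp = supported_bipartitions(t)
        assert splits[0] in bp

    def test_pp_boundary_strict(self):
        t, splits = self._tree()
        t.supports[splits[0]] = Support(pp=0.95)
        assert len(supported_bipartitions(t)) == 0

    def test_star_tree_has_no_splits(self):
        t = SupportTree.from_newick("(a,b,c,d);", False)
        assert t.splits() == set()

    def test_splits_conflict_logic(self):
        leaves = frozenset("abcdef")
        s1 = frozenset({"a", "b"})
        s2 = frozenset({"a", "c"})
        s3 = frozenset({"a", "b", "c"})
        assert splits_conflict(s1, s2, leaves)
        assert not splits_conflict(s1, s3, leaves)


class TestBootstrap:
    def test_identical_sequences_support_nothing(self):
        aln = Alignment([f"s{i}" for i in range(5)], ["ACGTACGT"] * 5)
        st_tree = bootstrap_support(aln, JC, n_reps=20, seed=1)
        assert st_tree.supports == {}

    def test_deep_split_gets_high_support(self):
        tree = SupportTree.from_newick(
            "((a1:0.01,a2:0.01,a3:0.01):0.25,(b1:0.01,b2:0.01,b3:0.01):0.25);",
            False)
        aln = simulate_alignment(tree, JC, 500, seed=9)
        st_tree = bootstrap_support(aln, JC, n_reps=100, seed=4)
        split = frozenset({"b1", "b2", "b3"})
        assert st_tree.supports[split].bs >= 95.0

    def test_same_seed_is_deterministic(self):
        tree = SupportTree.from_newick(
            "((a1:0.02,a2:0.02):0.1,(b1:0.02,b2:0.02):0.1,c:0.1);", False)
        aln = simulate_alignment(tree, JC, 300, seed=2)
        r1 = bootstrap_support(aln, JC, n_reps=50, seed=7)
        r2 = bootstrap_support(aln, JC, n_reps=50, seed=7)
        assert {k: v.bs for k, v in r1.supports.items()} == \
            {k: v.bs for k, v in r2.supports.items()}


class TestNewickSupports:
    def test_supports_roundtrip_as_internal_labels(self):
        t = SupportTree.from_newick(
            "((a:1,b:1)86:1,(c:1,d:1)65/0.99:1,e:1);")
        splits = {tuple(sorted(s)): v for s, v in t.supports.items()}
        # canonical side excludes the smallest leaf 'a'
        assert splits[("c", "d", "e")].bs == 86.0
        assert splits[("c", "d")].bs == 65.0
        assert splits[("c", "d")].pp == 0.99
        back = SupportTree.from_newick(t.newick())
        assert {tuple(sorted(s)): (v.bs, v.pp)
                for s, v in back.supports.items()} == \
            {tuple(sorted(s)): (v.bs, v.pp) for s, v in t.supports.items()}
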