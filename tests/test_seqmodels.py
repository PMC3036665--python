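"""Substitution models, distances, pruning likelihood, model choice."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esudelim.errors import (SaturationError, UndefinedDistanceError,
                             LabelMismatchError)
from esudelim.seqmodels import (Alignment, SubstitutionModel, alignment_stats,
                                collapse_haplotypes, corrected_distance,
                                distance_matrix, frame_stop_counts,
                                jc_correct, k2p_correct, p_distance,
                                select_model_aic, tree_log_likelihood)
from esudelim.trees import SupportTree
from esudelim.synthetic_data import simulate_alignment

JC = SubstitutionModel.jc()


def seq_pair_with_p(rng, length, p_target):
    """A random pair with roughly the requested mismatch proportion."""
    a = "".join(rng.choice(list("ACGT"), length))
    b = list(a)
    k = int(round(p_target * length))
    for i in rng.choice(length, size=k, replace=False):
        b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
    return a, "".join(b)


class TestAlignmentStats:
    def test_identical_sequences_have_no_variation(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        s = alignment_stats(aln)
        assert s.n_variable == 0 and s.n_parsimony_informative == 0

    def test_parsimony_informative_needs_two_states_twice(self):
        # site 1: A,A,C,C -> informative; site 2: A,A,C,A -> singleton
        aln = Alignment(list("abcd"), ["AA", "AA", "CC", "CA"])
        s = alignment_stats(aln)
        assert s.n_variable == 2
        assert s.n_parsimony_informative == 1

    def test_observed_tstv_pooled_over_pairs(self):
        # one A<->G transition and one C<->A transversion
        aln = Alignment(["x", "y"], ["AGAC", "GGAA"])
        assert alignment_stats(aln).tstv_observed == pytest.approx(1.0)

    def test_no_transversions_gives_nan(self):
        aln = Alignment(["x", "y"], ["AG", "GG"])
        assert math.isnan(alignment_stats(aln).tstv_observed)

    def test_gaps_and_ambiguities_not_counted_as_states(self):
        aln = Alignment(list("abcd"), ["A-", "AN", "AR", "AA"])
        s = alignment_stats(aln)
        assert s.n_variable == 0


class TestHaplotypeCollapse:
    def test_identical_sequences_share_haplotype(self):
        aln = Alignment(["A", "B", "C"], ["ACGT", "ACGT", "ACGA"])
        part, reps = collapse_haplotypes(aln)
        assert len(part.units) == 2
        assert part.assignment["A"] == part.assignment["B"]
        assert part.assignment["C"] != part.assignment["A"]
        assert reps.sequences == ["ACGT", "ACGA"]

    def test_all_distinct(self, rng):
        seqs = ["AAAA", "AAAC", "AACC", "ACCC"]
        part, _ = collapse_haplotypes(Alignment(list("abcd"), seqs))
        assert len(part.units) == 4

    def test_zero_within_species_diversity_gives_one_haplotype_each(self):
        from esudelim.synthetic_data import plocamionida_like, simulate_study
        cfg = plocamionida_like(seed=11, theta=0.0)
        bundle = simulate_study(cfg)
        part, _ = collapse_haplotypes(bundle.alignments["fast"])
        assert len(part.units) == 8  # = species count


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGT", "ACGT").p == 0.0

    def test_one_quarter(self):
        rec = p_distance("ACGT", "ACGA")
        assert rec.p == pytest.approx(0.25) and rec.n_compared == 4

    def test_pairwise_deletion(self):
        rec = p_distance("AC-T", "ACGA")
        assert rec.n_compared == 3 and rec.p == pytest.approx(1 / 3)

    def test_ambiguity_codes_excluded(self):
        rec = p_distance("ACRT", "ACGT")
        assert rec.n_compared == 3 and rec.p == 0.0

    def test_all_sites_excluded_raises(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("--", "AC")


class TestCorrectedDistance:
    def test_identical_is_zero_for_all_models(self):
        models = [JC, SubstitutionModel.k2p(3.0),
                  SubstitutionModel.hky(2.0, (0.3, 0.2, 0.2, 0.3), 0.2)]
        for m in models:
            assert corrected_distance("ACGTAC", "ACGTAC", m).d == 0.0

    def test_jc_closed_form(self):
        assert jc_correct(0.1) == pytest.approx(
            -(3 / 4) * math.log(1 - 4 * 0.1 / 3), abs=1e-12)

    def test_jc_saturation(self):
        with pytest.raises(SaturationError):
            jc_correct(0.76)

    def test_k2p_closed_form_matches_direct_evaluation(self):
        d = k2p_correct(0.08, 0.04)
        expect = -0.5 * math.log(1 - 2 * 0.08 - 0.04) \
            - 0.25 * math.log(1 - 2 * 0.04)
        assert d == pytest.approx(expect, abs=1e-12)

    def test_uniform_gtr_collapses_to_jc(self, rng):
        a, b = seq_pair_with_p(rng, 600, 0.08)
        gtr = SubstitutionModel("GTR", (0.25,) * 4, (1.0,) * 6)
        d_gtr = corrected_distance(a, b, gtr).d
        d_jc = corrected_distance(a, b, JC).d
        assert d_gtr == pytest.approx(d_jc, abs=1e-6)

    def test_correction_never_below_p(self, rng):
        # the guarantee applies when the model describes the data, which
        # is the pipeline's regime (models are estimated per locus)
        models = [JC, SubstitutionModel.k2p(4.0),
                  SubstitutionModel.hky(3.0, (0.35, 0.15, 0.15, 0.35), 0.3),
                  SubstitutionModel.gtr((2, 6, 1, 1, 7, 1),
                                        (0.3, 0.2, 0.2, 0.3), 0.2)]
        for m in models:
            for t in (0.02, 0.1, 0.3):
                tree = SupportTree.from_newick(
                    f"(a:{t / 2},b:{t / 2});", False)
                aln = simulate_alignment(tree, m, 800,
                                         seed=int(t * 1000) + 7)
                a, b = aln.sequence("a"), aln.sequence("b")
                p = p_distance(a, b).p
                if p == 0.0:
                    continue
                assert corrected_distance(a, b, m).d >= p - 1e-9

    def test_jc_strictly_increasing_in_p(self):
        ps = np.linspace(0.01, 0.7, 40)
        ds = [jc_correct(p) for p in ps]
        assert all(d2 > d1 for d1, d2 in zip(ds, ds[1:]))

    def test_numeric_route_matches_closed_form_for_k2p_pattern(self, rng):
        # HKY with equal frequencies IS K2P; the numeric optimiser must
        # agree with the closed form
        a, b = seq_pair_with_p(rng, 2000, 0.1)
        hky = SubstitutionModel.hky(4.0, (0.25,) * 4)
        num = corrected_distance(a, b, hky).d
        counts = p_distance(a, b)
        # closed form with kappa estimated implicitly; compare loosely
        assert num == pytest.approx(jc_correct(counts.p), rel=0.1)


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        aln = Alignment(["a", "b"], ["ACGTAC", "ACGTAC"])
        dm = distance_matrix(aln, JC)
        assert np.allclose(dm.values, 0.0)

    def test_monotone_with_p(self, rng):
        a = "".join(rng.choice(list("ACGT"), 300))
        b = list(a)
        c = list(a)
        idx = rng.choice(300, size=60, replace=False)
        for i in idx[:20]:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        for i in idx:
            c[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c[i]]
        aln = Alignment(["a", "b", "c"], [a, "".join(b), "".join(c)])
        dm = distance_matrix(aln, JC)
        assert dm.value("a", "b") < dm.value("a", "c")

    def test_star_tree_distances_near_2t(self):
        star = SupportTree.from_newick(
            "(a:0.05,b:0.05,c:0.05,d:0.05);", False)
        aln = simulate_alignment(star, JC, 50_000, seed=3)
        dm = distance_matrix(aln, JC)
        for x, y in itertools.combinations("abcd", 2):
            se = math.sqrt(0.1 / 50_000) * 3  # ~3 standard errors
            assert dm.value(x, y) == pytest.approx(0.1, abs=4 * se)

    def test_unit_summary_included_when_units_given(self):
        from esudelim.partition import UnitPartition
        aln = Alignment(["a1", "a2", "b1"],
                        ["ACGTACGTAA", "ACGTACGTAC", "ACTTACTTCC"])
        units = UnitPartition({"a1": "A", "a2": "A", "b1": "B"})
        dm, summary = distance_matrix(aln, JC, units=units)
        assert summary.labels == ["A", "B"]
        assert summary.diagonal("A") == pytest.approx(dm.value("a1", "a2"))
        assert np.isnan(summary.diagonal("B"))


class TestTreeLikelihood:
    def test_two_taxon_tree_equals_pairwise_likelihood(self, rng):
        a, b = seq_pair_with_p(rng, 400, 0.06)
        m = SubstitutionModel.hky(2.0, (0.3, 0.2, 0.2, 0.3), 0.3)
        rec = corrected_distance(a, b, m)
        aln = Alignment(["x", "y"], [a, b])
        # likelihood at the ML distance must beat nearby distances
        def lnl(d):
            t = SupportTree.from_newick(f"(x:{d / 2},y:{d / 2});", False)
            return tree_log_likelihood(aln, t, m)
        best = lnl(rec.d)
        assert best >= lnl(rec.d * 0.8) and best >= lnl(rec.d * 1.25)

    def test_pruning_equals_exhaustive_state_sum(self):
        aln = Alignment(["x", "y", "z"], ["ACT", "AGT", "GCA"])
        bl = {"x": 0.1, "y": 0.25, "z": 0.4}
        tree = SupportTree.from_newick(
            "(x:0.1,y:0.25,z:0.4);", False)
        ll = tree_log_likelihood(aln, tree, JC)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        P = {lab: JC.transition_probabilities(t) for lab, t in bl.items()}
        total = 0.0
        for site in range(3):
            s = 0.0
            for root in range(4):
                prod = 0.25
                for k, lab in enumerate(["x", "y", "z"]):
                    prod *= P[lab][root, idx[aln.sequences[k][site]]]
                s += prod
            total += math.log(s)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_pruning_with_invariant_mixture_against_direct_sum(self):
        m = SubstitutionModel.jc(p_inv=0.4)
        aln = Alignment(["x", "y"], ["AC", "AG"])
        tree = SupportTree.from_newick("(x:0.05,y:0.05);", False)
        ll = tree_log_likelihood(aln, tree, m)
        P = m.transition_probabilities(0.05 / 0.6)  # per-edge, scaled
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        total = 0.0
        for site in range(2):
            x, y = aln.sequences[0][site], aln.sequences[1][site]
            lik_var = sum(0.25 * P[r, idx[x]] * P[r, idx[y]]
                          for r in range(4))
            lik_inv = 0.25 * (x == y)
            total += math.log(0.4 * lik_inv + 0.6 * lik_var)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_zero_length_cherry_of_identical_sequence_keeps_lnl(self):
        aln = Alignment(["x", "y"], ["ACGTA", "ACTTA"])
        t1 = SupportTree.from_newick("(x:0.1,y:0.1);", False)
        base = tree_log_likelihood(aln, t1, JC)
        aln2 = Alignment(["x", "x2", "y"], ["ACGTA", "ACGTA", "ACTTA"])
        t2 = SupportTree.from_newick("((x:0.0,x2:0.0):0.1,y:0.1);", False)
        dup = tree_log_likelihood(aln2, t2, JC)
        assert dup == pytest.approx(base, abs=1e-10)

    def test_label_mismatch_lists_orphans(self):
        aln = Alignment(["x", "y"], ["AC", "AG"])
        tree = SupportTree.from_newick("(x:0.1,z:0.1);", False)
        with pytest.raises(LabelMismatchError, match="z"):
            tree_log_likelihood(aln, tree, JC)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_pruning_matches_enumeration_on_random_small_cases(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 5))
        length = int(rng.integers(1, 4))
        labels = [f"t{i}" for i in range(n)]
        seqs = ["".join(rng.choice(list("ACGTN-"), length))
                for _ in range(n)]
        aln = Alignment(labels, seqs)
        bl = np.round(rng.uniform(0.01, 0.5, size=n), 4)
        tips = ",".join(f"{l}:{b:.4f}" for l, b in zip(labels, bl))
        tree = SupportTree.from_newick(f"({tips});", False)
        ll = tree_log_likelihood(aln, tree, JC)
        # brute force with partial leaf states
        from esudelim._iupac import CODE_TO_MASK
        P = [JC.transition_probabilities(b) for b in bl]
        total = 0.0
        for site in range(length):
            s = 0.0
            for root in range(4):
                prod = 0.25
                for k in range(n):
                    mask = CODE_TO_MASK[seqs[k][site]]
                    prod *= sum(P[k][root, j] for j in range(4)
                                if mask & (1 << j))
                s += prod
            total += math.log(s)
        assert ll == pytest.approx(total, abs=1e-10)


class TestModelSelection:
    def test_jc_data_favours_jc_family(self):
        tree = SupportTree.from_newick(
            "((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05,(e:0.15,f:0.15):0.02);",
            False)
        aln = simulate_alignment(tree, JC, 1000, seed=7)
        best, fits = select_model_aic(aln)
        jc_best = min(f.aic for f in fits if f.model.family == "JC")
        assert jc_best <= best.aic + 2.0

    def test_unequal_gtr_beats_jc_by_more_than_2(self):
        gtr = SubstitutionModel.gtr((0.5, 12.0, 0.3, 0.8, 15.0, 1.0),
                                    (0.35, 0.15, 0.15, 0.35))
        tree = SupportTree.from_newick(
            "((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05,(e:0.15,f:0.15):0.02);",
            False)
        aln = simulate_alignment(tree, gtr, 1000, seed=8)
        best, fits = select_model_aic(aln)
        jc_aic = min(f.aic for f in fits if f.model.family == "JC")
        assert best.model.family in ("GTR", "TrN")
        assert jc_aic - best.aic > 2.0

    def test_invariant_alignment_won_by_jc_on_parsimony_of_k(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        best, fits = select_model_aic(aln, topology=SupportTree.from_newick(
            "((a:0.01,b:0.01):0.01,c:0.01,d:0.01);", False))
        assert best.model.family == "JC" and best.k == 0


class TestModelConstruction:
    def test_rate_matrix_rows_sum_to_zero_and_is_normalised(self):
        m = SubstitutionModel.gtr((2, 8, 1.5, 1.2, 8, 1),
                                  (0.25, 0.15, 0.20, 0.40), 0.4)
        q = m.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        pi = np.asarray(m.pi)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)

    def test_stationarity_of_transition_probabilities(self):
        m = SubstitutionModel.hky(3.0, (0.4, 0.1, 0.2, 0.3))
        p = m.transition_probabilities(0.7)
        pi = np.asarray(m.pi)
        assert np.allclose(pi @ p, pi, atol=1e-12)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(Exception):
            SubstitutionModel("GTR", (0.5, 0.5, 0.2, -0.2), (1,) * 6)
        with pytest.raises(Exception):
            SubstitutionModel.jc(p_inv=1.0)


class TestFrameCheck:
    def test_coding_sequence_has_stop_free_frame(self):
        # a short in-frame coding fragment under the invertebrate-like
        # mitochondrial code
        aln = Alignment(["s"], ["ATGGCTGCTGCTGGT"])
        stops = frame_stop_counts(aln)
        assert stops[0] == 0
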