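"""Distances, neighbor joining, GTR+I likelihood, NNI, Robinson-Foulds."""

import math
import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from dendropy.simulate import treesim

from cladeamp import fixtures, phylo
from cladeamp.alignment import Alignment
from cladeamp.phylo import (
    DistanceMatrix,
    SubstModel,
    distances,
    loglik,
    nj_tree,
    nni_search,
    rf_distance,
    tanglegram_pairs,
)


def _tree(nwk: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nwk, schema="newick")


def _additive_matrix(nwk: str):
    t = _tree(nwk)
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    labels = [x.label for x in taxa]
    d = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
    return t, DistanceMatrix(labels, d)


class TestDistances:
    def test_identical_rows_are_zero(self):
        msa = Alignment(["a", "b", "c"], ["ACGT" * 5] * 3)
        assert np.allclose(distances(msa).d, 0.0)

    def test_jc_closed_form_at_p_ten_percent(self):
        # 10% observed difference -> -(3/4) ln(1 - 4*0.1/3) = 0.1073
        row = "A" * 100
        other = "C" * 10 + "A" * 90
        msa = Alignment(["a", "b", "c"], [row, other, row])
        d = distances(msa)
        assert d.d[0, 1] == pytest.approx(0.10732, abs=1e-4)

    def test_saturated_pair_capped_and_flagged(self):
        msa = Alignment(["a", "b", "c"], ["A" * 40, "C" * 40, "A" * 40])
        d = distances(msa)
        assert d.d[0, 1] == 5.0
        assert ("a", "b") in d.saturated

    def test_gap_only_overlap_rejected(self):
        msa = Alignment(["a", "b", "c"], ["AA--", "--CC", "AACC"])
        with pytest.raises(ValueError, match="shared"):
            distances(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        )
        t = nj_tree(dm)
        bl = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert bl == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_matrix_recovers_topology(self):
        nwk = "((A:1,B:2):1,((C:1,D:1):2,E:4):1,F:3);"
        truth, dm = _additive_matrix(nwk)
        cmp = rf_distance(nj_tree(dm), truth)
        assert cmp.rf == 0

    def test_permutation_invariance(self):
        nwk = "((A:1,B:2):1,(C:1,D:1):2,(E:3,F:1):1);"
        _, dm = _additive_matrix(nwk)
        t1 = nj_tree(dm)
        order = [3, 0, 5, 1, 4, 2]
        dm2 = DistanceMatrix(
            [dm.taxa[i] for i in order], dm.d[np.ix_(order, order)]
        )
        assert rf_distance(t1, nj_tree(dm2)).rf == 0

    def test_agrees_with_dendropy_nj_on_additive_input(self):
        nwk = "(((A:1,B:1):1,(C:1,D:2):1):1,(E:1,F:1):2,(G:2,H:1):1);"
        truth, dm = _additive_matrix(nwk)
        # independent route: dendropy's own NJ implementation
        pdm = truth.phylogenetic_distance_matrix()
        dtree = pdm.nj_tree()
        assert rf_distance(nj_tree(dm), dtree).rf == 0


class TestLoglik:
    def test_zero_branch_single_column_equals_base_freq(self):
        msa = Alignment(["A", "B"], ["A", "A"])
        t = _tree("(A:0.0,B:0.0);")
        assert loglik(t, msa, SubstModel.jc()) == pytest.approx(math.log(0.25))

    def test_two_tip_closed_form(self):
        t_total = 0.3
        psame = 0.25 * (1.0 + 3.0 * math.exp(-4.0 * t_total / 3.0))
        msa = Alignment(["A", "B"], ["A", "A"])
        t = _tree(f"(A:{t_total},B:0.0);")
        assert loglik(t, msa, SubstModel.jc()) == pytest.approx(
            math.log(0.25 * psame)
        )

    def test_invariant_under_root_placement(self):
        msa = Alignment(["A", "B", "C"], ["ACGTTA", "ACGTAA", "TCGTAA"])
        m = SubstModel.jc()
        t1 = _tree("(A:0.1,B:0.2,C:0.3);")
        t2 = _tree("(A:0.04,(B:0.2,C:0.3):0.06);")
        assert loglik(t1, msa, m) == pytest.approx(loglik(t2, msa, m), abs=1e-9)

    def test_gtr_with_equal_rates_and_uniform_freqs_nests_jc(self):
        msa = Alignment(
            ["A", "B", "C", "D"],
            ["ACGTTAGC", "ACGTAAGC", "TCGTAACC", "TCGAAACC"],
        )
        t = _tree("((A:0.1,B:0.2):0.05,C:0.3,D:0.15);")
        gtr = SubstModel("GTR", np.ones(6), np.full(4, 0.25), 0.0)
        assert abs(loglik(t, msa, gtr) - loglik(t, msa, SubstModel.jc())) < 1e-8

    def test_invariant_sites_mixture_with_pinv(self):
        # constant column: L = (1-p) L_var + p * pi; variable column: (1-p) L_var
        msa_const = Alignment(["A", "B"], ["A", "A"])
        t = _tree("(A:0.2,B:0.0);")
        p = 0.3
        base = math.exp(loglik(t, msa_const, SubstModel.jc()))
        mixed = math.exp(loglik(t, msa_const, SubstModel.jc(p_inv=p)))
        assert mixed == pytest.approx((1 - p) * base + p * 0.25)

    def test_negative_branch_rejected(self):
        msa = Alignment(["A", "B"], ["A", "A"])
        with pytest.raises(ValueError, match="negative"):
            loglik(_tree("(A:-0.1,B:0.1);"), msa, SubstModel.jc())

    def test_tip_mismatch_rejected(self):
        msa = Alignment(["A", "X"], ["A", "A"])
        with pytest.raises(ValueError, match="tips"):
            loglik(_tree("(A:0.1,B:0.1);"), msa, SubstModel.jc())


TRUE_SIX = "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,(E:0.05,F:0.05):0.05);"


def _simulated_msa(nwk: str, length: int, seed: int) -> Alignment:
    tree = _tree(nwk)
    seqs = fixtures.evolve_sequences(
        tree, length, SubstModel.jc(), np.random.default_rng(seed)
    )
    ids = sorted(seqs)
    return Alignment(ids, [seqs[t] for t in ids])


class TestNNI:
    def test_optimal_start_returned_unchanged(self):
        msa = _simulated_msa(TRUE_SIX, 2000, seed=5)
        truth = _tree(TRUE_SIX)
        found, _ = nni_search(truth, msa, SubstModel.jc())
        assert rf_distance(found, truth).rf == 0

    def test_recovers_topology_from_one_move_away(self):
        msa = _simulated_msa(TRUE_SIX, 2000, seed=5)
        truth = _tree(TRUE_SIX)
        start = phylo._apply_nni(truth, 0, 0)
        assert rf_distance(start, truth).rf == 2
        found, ll = nni_search(start, msa, SubstModel.jc())
        assert rf_distance(found, truth).rf == 0

    def test_loglik_never_decreases_from_start(self):
        msa = _simulated_msa(TRUE_SIX, 400, seed=9)
        start = phylo._apply_nni(_tree(TRUE_SIX), 1, 1)
        ll0 = loglik(start, msa, SubstModel.jc())
        _, ll = nni_search(start, msa, SubstModel.jc())
        assert ll >= ll0

    def test_non_binary_start_rejected(self):
        msa = _simulated_msa(TRUE_SIX, 100, seed=1)
        bad = _tree("((A:1,B:1,C:1):1,(D:1,E:1):1,F:1);")
        with pytest.raises(ValueError, match="binary"):
            nni_search(bad, msa, SubstModel.jc())


def _random_binary_tree(n: int, rng: random.Random) -> str:
    frags = [f"T{i}" for i in range(n)]
    while len(frags) > 3:
        i, j = sorted(rng.sample(range(len(frags)), 2), reverse=True)
        a, b = frags.pop(i), frags.pop(j)
        frags.append(f"({a}:1,{b}:1)")
    return f"({frags[0]}:1,{frags[1]}:1,{frags[2]}:1);"


class TestRobinsonFoulds:
    def test_identical_trees_nrf_zero(self):
        t = "((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);"
        cmp = rf_distance(_tree(t), _tree(t))
        assert cmp.rf == 0 and cmp.nrf == 0.0

    def test_four_taxon_maximal_disagreement(self):
        a = _tree("((A:1,B:1):1,C:1,D:1);")
        b = _tree("((A:1,C:1):1,B:1,D:1);")
        cmp = rf_distance(a, b)
        assert cmp.rf == 2 and cmp.nrf == 1.0 and cmp.max_rf == 2

    def test_shared_tip_restriction(self):
        a = _tree("((A:1,B:1):1,(C:1,D:1):1,(E:1,X:1):1);")
        b = _tree("((A:1,B:1):1,(C:1,D:1):1,(E:1,Y:1):1);")
        cmp = rf_distance(a, b)
        assert cmp.n_shared_tips == 5 and cmp.rf == 0

    def test_fewer_than_four_shared_tips_rejected(self):
        with pytest.raises(ValueError, match="four"):
            rf_distance(_tree("(A:1,B:1,C:1);"), _tree("(A:1,B:1,C:1);"))

    def test_agreement_with_dendropy_on_random_pairs(self):
        """Symmetric difference matches dendropy's bipartition-based count
        on 100 random 8-tip tree pairs."""
        rng = random.Random(42)
        for _ in range(100):
            na, nb = _random_binary_tree(8, rng), _random_binary_tree(8, rng)
            cmp = rf_distance(_tree(na), _tree(nb))
            ns = dendropy.TaxonNamespace()
            ta = dendropy.Tree.get(data=na, schema="newick", taxon_namespace=ns)
            tb = dendropy.Tree.get(data=nb, schema="newick", taxon_namespace=ns)
            ta.encode_bipartitions()
            tb.encode_bipartitions()
            assert cmp.rf == treecompare.symmetric_difference(ta, tb)
            assert cmp.max_rf == 2 * (8 - 3)
            assert 0.0 <= cmp.nrf <= 1.0


class TestTanglegram:
    def test_identity_mapping_has_zero_crossings(self):
        t = "((A:1,B:1):1,(C:1,D:1):1);"
        mapping = {x: x for x in "ABCD"}
        pairs = tanglegram_pairs(_tree(t), _tree(t), mapping)
        left = [p[0] for p in pairs]
        right = [p[1] for p in pairs]
        assert phylo.count_crossings(left, right, mapping) == 0

    def test_unmapped_tip_marked_unassigned(self):
        t = "((A:1,B:1):1,(C:1,D:1):1);"
        mapping = {"A": "A", "B": "B", "C": "C"}
        pairs = tanglegram_pairs(_tree(t), _tree(t), mapping)
        cat = {r: c for _, r, c in pairs}
        assert cat["D"] == "unassigned"

    def test_categories_pass_through(self):
        t = "((A:1,B:1):1,(C:1,D:1):1);"
        mapping = {x: x for x in "ABCD"}
        cats = {"A": "one_to_one", "B": "conflict", "C": "less_specific",
                "D": "one_to_one"}
        pairs = tanglegram_pairs(_tree(t), _tree(t), mapping, cats)
        assert {r: c for _, r, c in pairs} == cats


class TestModelFit:
    def test_optimize_model_improves_or_matches_loglik(self):
        msa = _simulated_msa(TRUE_SIX, 600, seed=2)
        t = _tree(TRUE_SIX)
        start = SubstModel("GTR", np.ones(6), np.full(4, 0.25), 0.0)
        fitted = phylo.optimize_model(t, msa, start, rounds=1)
        assert loglik(t, msa, fitted) >= loglik(t, msa, start) - 1e-6
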