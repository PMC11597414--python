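"""NJ reconstruction and F/M pattern classification."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duimito.phylo_patterns import (SexTree, classify_patterns, nj_tree,
                                    parse_tip_label, pattern_summary)


def _labels_of(calls):
    return {c.species: c.label for c in calls}


class TestNjTree:
    def test_three_taxa_closed_form(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=4 -> branch lengths 1,1,3
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        st_ = nj_tree(d, ["A", "B", "C"])
        pdm = st_.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in st_.tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(2.0)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(4.0)

    def test_additive_five_taxon_matrix_recovers_topology(self):
        # distances from ((A:1,B:2):1,(C:1,D:2):2,E:4)
        newick = "((A:1,B:2):1,(C:1,D:2):2,E:4);"
        true = dendropy.Tree.get(data=newick, schema="newick")
        pdm = true.phylogenetic_distance_matrix()
        taxa = sorted(true.taxon_namespace, key=lambda t: t.label)
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = pdm.distance(taxa[i], taxa[j])
        st_ = nj_tree(d, [t.label for t in taxa])
        tns = true.taxon_namespace
        est = dendropy.Tree.get(data=st_.tree.as_string(schema="newick"),
                                schema="newick", taxon_namespace=tns)
        est.encode_bipartitions()
        true.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(true, est) == 0

    def test_identical_rows_zero_cherry(self):
        d = np.array([[0, 0, 3, 3], [0, 0, 3, 3],
                      [3, 3, 0, 0], [3, 3, 0, 0]], float)
        st_ = nj_tree(d, ["A", "B", "C", "D"])
        node = st_.tree.mrca(taxon_labels=["A", "B"])
        for leaf in node.leaf_iter():
            assert (leaf.edge.length or 0.0) == pytest.approx(0.0)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, list("ABC"))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_additive_trees_recovered(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 12))
        taxa = [f"T{i}" for i in range(n)]
        true = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            rng=__import__("random").Random(seed))
        for i, leaf in enumerate(true.leaf_node_iter()):
            leaf.taxon.label = taxa[i]
        for edge in true.preorder_edge_iter():
            if edge.length is None or edge.length <= 0:
                edge.length = 0.1
        pdm = true.phylogenetic_distance_matrix()
        tx = {t.label: t for t in true.taxon_namespace if t.label in taxa}
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = pdm.distance(tx[taxa[i]], tx[taxa[j]])
        est_st = nj_tree(d, taxa)
        est = dendropy.Tree.get(data=est_st.tree.as_string(schema="newick"),
                                schema="newick",
                                taxon_namespace=true.taxon_namespace)
        est.encode_bipartitions()
        true.encode_bipartitions()
        true.is_rooted = False
        est.is_rooted = False
        true.update_bipartitions()
        est.update_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(true, est) == 0


class TestClassification:
    def test_taxon_joining_forced_by_cherries(self):
        st_ = SexTree.from_newick("(((A__F,A__M),(B__F,B__M)),OUT);",
                                  outgroup="OUT")
        calls = classify_patterns(st_)
        assert _labels_of(calls) == {"A": "taxon_joining", "B": "taxon_joining"}

    def test_gender_joining_reciprocal_monophyly(self):
        st_ = SexTree.from_newick("(((A__F,B__F),(A__M,B__M)),OUT);",
                                  outgroup="OUT")
        assert _labels_of(classify_patterns(st_)) == \
            {"A": "gender_joining", "B": "gender_joining"}

    def test_masculinization_topology(self):
        st_ = SexTree.from_newick("((((Gdi__F,Gdi__M),Gva__F),Gva__M),OUT);",
                                  outgroup="OUT")
        labels = _labels_of(classify_patterns(st_))
        assert labels == {"Gdi": "masculinization_signature",
                          "Gva": "masculinization_signature"}

    def test_indeterminate_for_interleaved_topology(self):
        # F and M tips interleave across species: no rule applies
        st_ = SexTree.from_newick(
            "(((A__F,B__M),(A__M,B__F)),OUT);", outgroup="OUT")
        labels = _labels_of(classify_patterns(st_))
        assert labels == {"A": "indeterminate", "B": "indeterminate"}

    def test_species_missing_one_sex_skipped(self):
        st_ = SexTree.from_newick("(((A__F,A__M),B__F),OUT);", outgroup="OUT")
        with pytest.warns(UserWarning, match="missing one sex"):
            calls = classify_patterns(st_)
        assert _labels_of(calls) == {"A": "taxon_joining"}

    def test_invariant_under_child_rotation(self):
        newicks = ["(((A__F,A__M),(B__F,B__M)),OUT);",
                   "((( A__M,A__F),(B__M,B__F)),OUT);".replace(" ", ""),
                   "(OUT,((B__F,B__M),(A__F,A__M)));"]
        results = []
        for nwk in newicks:
            st_ = SexTree.from_newick(nwk, outgroup="OUT")
            results.append(_labels_of(classify_patterns(st_)))
        assert results[0] == results[1] == results[2]


class TestSummaryAndLabels:
    def test_label_parsing(self):
        assert parse_tip_label("Gafrarium_dispar__F") == ("Gafrarium_dispar", "F")
        assert parse_tip_label("OUT") is None
        assert parse_tip_label("X__Z") is None

    def test_tally(self):
        st_ = SexTree.from_newick("(((A__F,A__M),(B__F,B__M)),OUT);",
                                  outgroup="OUT")
        tally = pattern_summary(classify_patterns(st_))
        assert tally == {"taxon_joining": ["A", "B"]}

    def test_empty_input_empty_tally(self):
        assert pattern_summary([]) == {}
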