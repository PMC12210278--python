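"""Bipartitions, consensus degree, distances, monophyly, consensus trees."""

import dendropy
import numpy as np
import pytest

from taxodelim.errors import InvariantError
from taxodelim.seqio import newick_string, read_newick
from taxodelim.simulate import random_resolved_tree
from taxodelim.treestats import (
    bipartitions,
    consensus_degree,
    ed_matrix,
    majority_consensus,
    midpoint_root,
    monophyly_report,
    prune_leaves,
    rf_distance,
    root_with_outgroup,
    support_summary,
)



def nwk(s: str):
    return read_newick(s, is_string=True)


def dendropy_rf(t1, t2) -> int:
    """Independent RF via dendropy on the serialized trees."""
    ns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=newick_string(t1), schema="newick", taxon_namespace=ns)
    d2 = dendropy.Tree.get(data=newick_string(t2), schema="newick", taxon_namespace=ns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestBipartitions:
    def test_single_internal_split(self):
        bips = bipartitions(nwk("((A,B),(C,D));"))
        assert {frozenset(b.side) for b in bips} == {frozenset("CD")}

    def test_caterpillar_has_l_minus_3(self):
        t = nwk("(A,(B,(C,(D,(E,F)))));")
        assert len(bipartitions(t)) == 3

    def test_too_few_leaves_rejected(self):
        with pytest.raises(InvariantError):
            bipartitions(nwk("((A,B),C);"))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_binary_trees_have_l_minus_3(self, seed):
        n = 5 + seed
        t = random_resolved_tree([f"x{i}" for i in range(n)], seed=seed)
        assert len(bipartitions(t)) == n - 3


class TestConsensusDegreeAndRf:
    def test_identical_trees_cd_100(self):
        t = random_resolved_tree([f"x{i}" for i in range(9)], seed=0)
        rep = consensus_degree(t, t.copy())
        assert rep.cd == 100.0 and rep.n_shared == rep.denominator == 6

    def test_six_leaf_nni_pair(self):
        # one NNI across the {C,D} edge swaps D with (E,F): splits {A,B}
        # and {E,F} survive, {C,D} is replaced, so 2 of 3 are shared
        t1 = nwk("((A,B),((C,D),(E,F)));")
        t2 = nwk("((A,B),((C,(E,F)),D));")
        rep = consensus_degree(t1, t2)
        assert rep.n_shared == 2 and rep.denominator == 3
        assert rep.cd == pytest.approx(100 * 2 / 3)
        assert rf_distance(t1, t2) == 2 == dendropy_rf(t1, t2)

    def test_leaf_set_mismatch_lists_difference(self):
        with pytest.raises(InvariantError, match="only in first.*E"):
            consensus_degree(nwk("((A,B),(C,E));"), nwk("((A,B),(C,D));"))

    def test_maximally_different_caterpillars(self):
        # caterpillars with interleaved leaf orders share no splits
        t1 = nwk("(a,(b,(c,(d,(e,(f,(g,h)))))));")
        t2 = nwk("(a,(e,(c,(g,(b,(f,(d,h)))))));")
        L = 8
        assert rf_distance(t1, t2) == 2 * (L - 3) == dendropy_rf(t1, t2)
        assert consensus_degree(t1, t2).cd == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_cd_rf_identity_and_dendropy_agreement(self, seed):
        """cd = 100(1 - rf/(2(L-3))) with RF cross-checked against dendropy."""
        L = 8
        t1 = random_resolved_tree([f"x{i}" for i in range(L)], seed=seed)
        t2 = random_resolved_tree([f"x{i}" for i in range(L)], seed=seed + 100)
        rf = rf_distance(t1, t2)
        assert rf == dendropy_rf(t1, t2)
        assert consensus_degree(t1, t2).cd == pytest.approx(100 * (1 - rf / (2 * (L - 3))))


class TestEdMatrix:
    def test_path_sums(self):
        m = ed_matrix(nwk("((A:1,B:1):1,C:2);"))
        assert m.value("A", "B") == pytest.approx(2.0)
        assert m.value("A", "C") == pytest.approx(4.0)

    def test_ultrametric_root_crossing_pairs_equidistant(self):
        m = ed_matrix(nwk("((A:1,B:1):1,(C:0.5,D:0.5):1.5);"))
        for a in "AB":
            for b in "CD":
                assert m.value(a, b) == pytest.approx(4.0)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(InvariantError, match="branch length"):
            ed_matrix(nwk("((A:1,B),C:2);"))

    @pytest.mark.parametrize("seed", range(5))
    def test_triangle_inequality(self, seed):
        t = random_resolved_tree([f"x{i}" for i in range(8)], seed=seed)
        m = ed_matrix(t)
        v = m.values
        n = len(m.labels)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9

    def test_permutation_equivariance(self):
        t1 = nwk("((A:1,B:2):1,(C:1,D:3):2);")
        t2 = nwk("((D:3,C:1):2,(B:2,A:1):1);")
        m1, m2 = ed_matrix(t1), ed_matrix(t2)
        for a in "ABCD":
            for b in "ABCD":
                assert m1.value(a, b) == pytest.approx(m2.value(a, b))


class TestSupportSummary:
    def test_half_below(self):
        t = nwk("((A,B)60,((C,D)80,E));")
        s = support_summary(t, 70)
        assert s == {"n_internal": 2, "n_below": 1, "fraction_below": 0.5}

    def test_none_below_when_all_100(self):
        t = nwk("((A,B)100,((C,D)100,E)100);")
        assert support_summary(t, 70)["fraction_below"] == 0.0

    def test_unsupported_tree_rejected(self):
        with pytest.raises(InvariantError, match="no supported"):
            support_summary(nwk("((A,B),(C,D));"), 70)


class TestMonophyly:
    def test_clean_split_both_monophyletic(self):
        rep = monophyly_report(
            nwk("((A1,A2),(B1,B2));"), {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        )
        assert all(v["monophyletic"] for v in rep.values())

    def test_interleaved_both_polyphyletic(self):
        rep = monophyly_report(
            nwk("((A1,B1),(A2,B2));"), {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        )
        assert not any(v["monophyletic"] for v in rep.values())
        assert rep["A"]["smallest_containing_clade"] == 4

    def test_singleton_taxon_is_monophyletic(self):
        rep = monophyly_report(nwk("((A1,B1),C1);"), {"A1": "A", "B1": "B", "C1": "C"})
        assert all(v["monophyletic"] for v in rep.values())

    def test_unmapped_leaf_rejected(self):
        with pytest.raises(InvariantError, match="unmapped"):
            monophyly_report(nwk("((A1,B1),C1);"), {"A1": "A", "B1": "B"})

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_clade_scan(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"x{i}" for i in range(9)]
        t = random_resolved_tree(labels, seed=seed)
        mapping = {lab: f"T{int(rng.integers(3))}" for lab in labels}
        rep = monophyly_report(t, mapping)
        # brute force: collect every clade's leaf set by path enumeration
        clades = []
        for node in t.root.preorder():
            clades.append(frozenset(leaf.label for leaf in node.leaves()))
        for taxon, info in rep.items():
            members = frozenset(l for l, tx in mapping.items() if tx == taxon)
            assert info["monophyletic"] == (members in clades)


class TestMajorityConsensus:
    def test_identical_trees_full_recovery(self):
        t = random_resolved_tree([f"x{i}" for i in range(7)], seed=1)
        cons = majority_consensus([t.copy(), t.copy(), t.copy()])
        assert {b.side for b in bipartitions(cons)} == {b.side for b in bipartitions(t)}
        counts = [n.recovery for n in cons.internal_nodes()]
        assert all(c == 3 for c in counts)

    def test_disjoint_trees_give_star(self):
        t1 = nwk("((A,B),(C,(D,E)));")
        t2 = nwk("((A,C),(E,(B,D)));")
        assert {b.side for b in bipartitions(t1)} & {b.side for b in bipartitions(t2)} == set()
        cons = majority_consensus([t1, t2])
        assert len(cons.internal_nodes()) == 1  # root only

    def test_three_of_four_bipartition_retained_with_count(self):
        shared = "(((A,B),C),(D,(E,F)));"  # contains split {A,B}
        other = "(((A,C),B),(D,(E,F)));"
        trees = [nwk(shared), nwk(shared), nwk(shared), nwk(other)]
        cons = majority_consensus(trees)
        # tally oracle: {E,F} and {D,E,F} occur 4 times, {A,B} 3 times and
        # {A,C} only once; splits are orientation-free, so index each clade
        # by whichever side excludes leaf A
        universe = frozenset("ABCDEF")
        by_split = {}
        for node in cons.internal_nodes():
            clade = frozenset(n.label for n in node.leaves())
            side = universe - clade if "A" in clade else clade
            by_split[side] = node.recovery
        assert by_split[universe - frozenset("AB")] == 3  # the {A,B} split
        assert by_split[frozenset("EF")] == 4
        assert universe - frozenset("AC") not in by_split

    def test_consensus_subset_of_input_bipartitions(self):
        trees = [random_resolved_tree([f"x{i}" for i in range(8)], seed=s) for s in range(4)]
        cons = majority_consensus(trees)
        union = set()
        for t in trees:
            union |= {b.side for b in bipartitions(t)}
        assert {b.side for b in bipartitions(cons)} <= union


class TestRooting:
    def test_outgroup_rooting_preserves_topology_and_distances(self):
        t = nwk("((A:1,B:2):1,(C:1,(D:1,E:1):1):2);")
        r = root_with_outgroup(t, "D")
        assert rf_distance(t, r) == 0
        assert ed_matrix(t).value("A", "E") == pytest.approx(ed_matrix(r).value("A", "E"))
        assert r.root.children[0].label == "D" or r.root.children[1].label == "D"

    def test_midpoint_rooting_preserves_topology(self):
        t = nwk("((A:1,B:2):1,(C:1,(D:4,E:1):1):2);")
        m = midpoint_root(t)
        assert rf_distance(t, m) == 0
        # D ends the diameter; its two root-side path halves are equal
        dm = ed_matrix(m)
        diam = max(
            dm.value(a, b) for a in dm.labels for b in dm.labels
        )
        depths = {}
        for leaf in m.leaves():
            d, node = 0.0, leaf
            while node.parent is not None:
                d += node.length or 0.0
                node = node.parent
            depths[leaf.label] = d
        assert max(depths.values()) == pytest.approx(diam / 2)

    def test_prune_leaves(self):
        t = nwk("((A:1,B:2):1,(C:1,(D:1,E:1):1):2);")
        p = prune_leaves(t, ["D"])
        assert sorted(p.leaf_labels()) == ["A", "B", "C", "E"]
        # E inherits D's removed parent edge
        assert ed_matrix(p).value("C", "E") == pytest.approx(ed_matrix(t).value("C", "E"))
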