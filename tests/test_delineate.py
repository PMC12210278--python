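"""Separation statistics, threshold derivation and rank delineation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from taxodelim.core import LabeledMatrix
from taxodelim.delineate import (
    TaxonPartition,
    ThresholdRule,
    compare_partitions,
    delineate_rank,
    derive_threshold,
    hierarchical_delineate,
    intra_inter_split,
    welch_t_test,
    P_FLOOR,
)
from taxodelim.errors import DelineationError, InvariantError
from taxodelim.seqio import read_newick
from taxodelim.treestats import ed_matrix

from oracles import ari_oracle, t_two_sided_p, threshold_scan_oracle


def sim_matrix(labels, values):
    return LabeledMatrix(labels, np.asarray(values, float), kind="similarity", scale="fraction")


def partition(rank, mapping):
    return TaxonPartition.from_mapping(rank, mapping)


class TestIntraInterSplit:
    def test_two_groups_of_two(self):
        labels = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 0.5)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.8
        np.fill_diagonal(v, 1.0)
        rep = intra_inter_split(
            sim_matrix(labels, v), partition("g", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        )
        assert sorted(rep.intra) == [0.8, 0.8]
        assert list(rep.inter) == [0.5] * 4

    def test_all_singletons_flagged(self):
        labels = ["a", "b"]
        v = [[1.0, 0.4], [0.4, 1.0]]
        rep = intra_inter_split(sim_matrix(labels, v), partition("g", {"a": "A", "b": "B"}))
        assert rep.all_singletons and rep.intra.size == 0
        assert rep.group_summaries["A"]["n"] == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(InvariantError, match="not in matrix"):
            intra_inter_split(
                sim_matrix(["a"], [[1.0]]), partition("g", {"a": "A", "z": "A"})
            )

    @given(st.integers(0, 2**31 - 1))
    def test_sample_sizes_match_pair_counts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        labels = [f"t{i}" for i in range(n)]
        v = rng.uniform(0, 0.9, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        groups = {lab: f"G{int(rng.integers(1, 4))}" for lab in labels}
        part = partition("g", groups)
        rep = intra_inter_split(sim_matrix(labels, v), part)
        expected_intra = sum(
            math.comb(len(m), 2) for m in part.groups.values()
        )
        assert rep.intra.size == expected_intra
        assert rep.intra.size + rep.inter.size == math.comb(n, 2)


class TestWelch:
    def test_identical_samples_t_zero_p_one(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and not res.floored

    def test_matches_quadrature_oracle_on_grid(self):
        """Welch p equals numerically integrated t tail to 1e-10."""
        shapes = [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]),
            ([0.1, 0.2, 0.15, 0.3], [0.5, 0.55, 0.52]),
            (list(np.linspace(0, 1, 10)), list(np.linspace(0.2, 1.4, 7))),
            ([5, 6, 7, 8, 9.0], [5.5, 6.5, 7.5]),
            ([0.0, 0.1], [0.05, 0.2, 0.3]),
        ]
        for x, y in shapes:
            res = welch_t_test(x, y)
            assert res.p == pytest.approx(t_two_sided_p(res.t, res.df), abs=1e-10)

    def test_floor_on_disjoint_band_samples(self):
        rng = np.random.default_rng(0)
        intra = rng.uniform(0.62, 0.84, 300)
        inter = rng.uniform(0.51, 0.60, 300)
        res = welch_t_test(intra, inter)
        assert res.floored and res.p == P_FLOOR
        assert res.p_display == "< 2.2e-16"

    def test_degenerate_samples_rejected(self):
        with pytest.raises(InvariantError):
            welch_t_test([1.0], [1.0, 2.0])


class TestDeriveThreshold:
    def test_separable_midpoint(self):
        out = derive_threshold([0.7, 0.8], [0.5, 0.55], "similarity")
        assert out == {"cutoff": pytest.approx(0.625), "misclassified": 0}

    def test_distance_direction(self):
        out = derive_threshold([0.2, 0.3], [0.6, 0.9], "distance")
        assert out["cutoff"] == pytest.approx(0.45) and out["misclassified"] == 0

    @given(st.integers(0, 2**31 - 1))
    def test_interleaved_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        intra = rng.uniform(0.4, 0.7, 15)
        inter = rng.uniform(0.5, 0.8, 20)
        out = derive_threshold(intra, inter, "similarity")
        assert out["misclassified"] == threshold_scan_oracle(intra, inter, "similarity")
        assert out["misclassified"] > 0

    def test_empty_sample_rejected(self):
        with pytest.raises(InvariantError):
            derive_threshold([], [0.5], "similarity")


class TestDelineateRank:
    def tree(self):
        return read_newick("((A:1,B:1)95:1,(C:1,D:1)95:1);", is_string=True)

    def matrices(self):
        labels = ["A", "B", "C", "D"]
        v = np.full((4, 4), 0.5)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.8
        np.fill_diagonal(v, 1.0)
        return {"AAI": sim_matrix(labels, v)}

    def test_two_clades_recovered(self):
        part = delineate_rank(
            self.tree(), [ThresholdRule("AAI", "similarity", 0.7)], self.matrices(), 70
        )
        assert sorted(map(sorted, part.groups.values())) == [["A", "B"], ["C", "D"]]
        # matches the 4-leaf enumeration: no higher clade satisfies the rule
        for prov in part.provenance.values():
            assert prov["min_intra_AAI"] >= 0.7

    def test_cutoff_above_everything_gives_singletons(self):
        part = delineate_rank(
            self.tree(), [ThresholdRule("AAI", "similarity", 0.95)], self.matrices(), 70
        )
        assert part.n_groups == 4

    def test_zero_cutoff_gives_single_group(self):
        part = delineate_rank(
            self.tree(), [ThresholdRule("AAI", "similarity", 0.0)], self.matrices(), 70
        )
        assert part.n_groups == 1 and len(next(iter(part.groups.values()))) == 4

    def test_low_support_forces_descent(self):
        t = read_newick("((A:1,B:1)50:1,(C:1,D:1)95:1);", is_string=True)
        part = delineate_rank(
            t, [ThresholdRule("AAI", "similarity", 0.7)], self.matrices(), 70
        )
        groups = sorted(map(sorted, part.groups.values()))
        assert ["A"] in groups and ["B"] in groups and ["C", "D"] in groups

    def test_nan_entries_force_descent(self):
        labels = ["A", "B", "C", "D"]
        v = np.full((4, 4), 0.9)
        v[0, 1] = v[1, 0] = np.nan
        np.fill_diagonal(v, 1.0)
        part = delineate_rank(
            self.tree(), [ThresholdRule("AAI", "similarity", 0.7)],
            {"AAI": sim_matrix(labels, v)}, 70,
        )
        groups = sorted(map(sorted, part.groups.values()))
        assert ["A"] in groups and ["B"] in groups

    def test_groups_are_clades_and_cover_leaves(self, small_truth, small_aai):
        truth, _prots = small_truth
        from taxodelim.treestats import monophyly_report

        ed = ed_matrix(truth.tree)
        part = delineate_rank(
            truth.tree,
            [ThresholdRule("AAI", "similarity", 0.6), ThresholdRule("ED", "distance", 0.5)],
            {"AAI": small_aai, "ED": ed},
            70,
        )
        assert part.leaf_universe == frozenset(truth.tree.leaf_labels())
        rep = monophyly_report(truth.tree, part.group_of())
        assert all(v["monophyletic"] for v in rep.values())

    def test_monotone_refinement_in_cutoff(self, small_truth, small_aai):
        truth, _prots = small_truth
        previous = None
        for cutoff in (0.3, 0.5, 0.65, 0.8):
            part = delineate_rank(
                truth.tree, [ThresholdRule("AAI", "similarity", cutoff)],
                {"AAI": small_aai}, 70,
            )
            if previous is not None:
                # every new group fits inside some previous group
                for members in part.groups.values():
                    assert any(members <= old for old in previous.groups.values())
            previous = part


class TestHierarchical:
    def test_equal_rules_reproduce_family_partition(self, small_truth, small_aai):
        truth, _prots = small_truth
        ed = ed_matrix(truth.tree)
        rules = [ThresholdRule("AAI", "similarity", 0.6), ThresholdRule("ED", "distance", 0.5)]
        parts = hierarchical_delineate(truth.tree, rules, rules, {"AAI": small_aai, "ED": ed})
        fam_groups = set(map(frozenset, parts["family"].groups.values()))
        gen_groups = set(map(frozenset, parts["genus"].groups.values()))
        assert fam_groups == gen_groups

    def test_looser_genus_rules_rejected(self, small_truth, small_aai):
        truth, _prots = small_truth
        ed = ed_matrix(truth.tree)
        with pytest.raises(DelineationError, match="looser"):
            hierarchical_delineate(
                truth.tree,
                [ThresholdRule("AAI", "similarity", 0.7), ThresholdRule("ED", "distance", 0.4)],
                [ThresholdRule("AAI", "similarity", 0.6), ThresholdRule("ED", "distance", 0.5)],
                {"AAI": small_aai, "ED": ed},
            )

    def test_genus_refines_family_on_planted_data(self, small_truth, small_aai):
        truth, _prots = small_truth
        ed = ed_matrix(truth.tree)
        parts = hierarchical_delineate(
            truth.tree,
            [ThresholdRule("AAI", "similarity", 0.6), ThresholdRule("ED", "distance", 0.5)],
            [ThresholdRule("AAI", "similarity", 0.7), ThresholdRule("ED", "distance", 0.4)],
            {"AAI": small_aai, "ED": ed},
        )
        fam_of = parts["family"].group_of()
        for members in parts["genus"].groups.values():
            assert len({fam_of[leaf] for leaf in members}) == 1
        assert compare_partitions(parts["family"], truth.family_partition)["ari"] == 1.0
        assert compare_partitions(parts["genus"], truth.genus_partition)["ari"] == 1.0


class TestComparePartitions:
    def test_identical_partitions(self):
        p = partition("r", {"a": "X", "b": "X", "c": "Y"})
        out = compare_partitions(p, p)
        assert out["ari"] == 1.0 and out["n_agree_pairs"] == 3

    def test_singletons_vs_one_group(self):
        p = partition("r", {"a": "A", "b": "B", "c": "C"})
        q = partition("r", {"a": "X", "b": "X", "c": "X"})
        assert compare_partitions(p, q)["ari"] == 0.0

    def test_universe_mismatch_rejected(self):
        with pytest.raises(InvariantError):
            compare_partitions(
                partition("r", {"a": "A"}), partition("r", {"b": "B"})
            )

    @given(st.integers(0, 2**31 - 1))
    def test_matches_contingency_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        leaves = [f"t{i}" for i in range(n)]
        p = partition("r", {l: f"P{int(rng.integers(1, 4))}" for l in leaves})
        q = partition("r", {l: f"Q{int(rng.integers(1, 4))}" for l in leaves})
        got = compare_partitions(p, q)["ari"]
        pm, qm = p.group_of(), q.group_of()
        expected = ari_oracle([pm[l] for l in leaves], [qm[l] for l in leaves])
        assert got == pytest.approx(expected)
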