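"""Identity, OG assignment, gene trees, curation, umbrellas, concordance."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

import dehalopan as dp
from dehalopan.genome_io import ProteinSeq
from dehalopan.og_classification import (
    GeneTree,
    IdentityMatrix,
    assign_ogs,
    build_nj_tree,
    clade_concordance,
    curate_partition,
    detect_umbrellas,
    pairwise_identity,
    singleton_label,
)

PARENT = "M" + ("ACDEFGHIKLMNPQRSTVWY" * 10)[:199]  # 200 aa


def _tree(newick: str) -> GeneTree:
    t = TreeNode.read(io.StringIO(newick))
    return GeneTree(tree=t, newick=newick)


def _matrix(ids, pairs, default=50.0):
    n = len(ids)
    m = np.full((n, n), default)
    np.fill_diagonal(m, 100.0)
    idx = {x: i for i, x in enumerate(ids)}
    for a, b, v in pairs:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
    return IdentityMatrix(list(ids), m)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity(PARENT, PARENT) == 100.0

    def test_engineered_ninety_percent(self):
        child = dp.mutate_to_identity(PARENT, 0.90, 17)
        assert pairwise_identity(PARENT, child) == pytest.approx(90.0)

    def test_free_end_gaps_ignore_extension(self):
        assert pairwise_identity(PARENT, PARENT + "AAAAAAAAAA") == 100.0

    def test_symmetry(self):
        child = dp.mutate_to_identity(PARENT, 0.8, 23)
        assert pairwise_identity(PARENT, child) == pytest.approx(
            pairwise_identity(child, PARENT)
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", PARENT)


def brute_force_components(ids, matrix, threshold):
    """Independent union-find oracle over the thresholded identity graph."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    idx = {x: i for i, x in enumerate(ids)}
    for a in ids:
        for b in ids:
            if a < b and matrix[idx[a], idx[b]] >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for x in ids:
        groups.setdefault(find(x), set()).add(x)
    return {frozenset(g) for g in groups.values()}


class TestAssignOGs:
    def test_three_sequences_one_og(self):
        m = _matrix(["a", "b", "c"], [("a", "b", 92), ("b", "c", 91), ("a", "c", 93)])
        part = assign_ogs(m)
        assert len(set(part.assignment.values())) == 1

    def test_single_linkage_chains(self):
        m = _matrix(["a", "b", "c"], [("a", "b", 92), ("b", "c", 91), ("a", "c", 85)])
        part = assign_ogs(m)
        assert len(set(part.assignment.values())) == 1

    def test_below_cutoff_makes_lettered_singletons(self):
        m = _matrix(["a", "b"], [("a", "b", 89)])
        part = assign_ogs(m)
        assert part.assignment == {"a": "A", "b": "B"}

    def test_numbering_by_size_then_member(self):
        m = _matrix(
            ["a", "b", "c", "d", "e", "f"],
            [("a", "b", 95), ("b", "c", 95), ("d", "e", 95)],
        )
        part = assign_ogs(m)
        assert part.assignment["a"] == "OG1"  # size-3 group first
        assert part.assignment["d"] == "OG2"
        assert part.assignment["f"] == "A"

    @given(
        st.integers(min_value=2, max_value=7).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(min_value=50, max_value=100), min_size=n, max_size=n),
                min_size=n,
                max_size=n,
            )
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_union_find_oracle(self, rows):
        n = len(rows)
        m = np.array(rows, dtype=float)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        ids = [f"s{i}" for i in range(n)]
        part = assign_ogs(IdentityMatrix(ids, m), threshold=90)
        got = {frozenset(v) for v in part.groups().values()}
        assert got == brute_force_components(ids, m, 90)


def test_singleton_labels_spreadsheet_style():
    assert [singleton_label(i) for i in (0, 1, 25, 26, 27)] == ["A", "B", "Z", "AA", "AB"]


class TestBuildNJTree:
    def _planted_quartet(self):
        a = PARENT
        b = dp.mutate_to_identity(a, 0.95, 31)
        c = dp.mutate_to_identity(a, 0.70, 32)
        d = dp.mutate_to_identity(c, 0.95, 33)
        prots = [
            ProteinSeq(protein_id=n, residues=s)
            for n, s in zip("ABCD", (a, b, c, d))
        ]
        return prots

    def test_recovers_planted_split_with_support(self):
        prots = self._planted_quartet()
        ident = dp.identity_matrix(prots)
        aln = {p.protein_id: p.residues for p in prots}
        gt = build_nj_tree(ident, alignment=aln, bootstrap=100, seed=5)
        split = frozenset({"A", "B"})
        assert split in gt.supports
        assert gt.supports[split] >= 95

    def test_three_sequences_single_topology(self):
        prots = self._planted_quartet()[:3]
        gt = build_nj_tree(dp.identity_matrix(prots))
        assert gt.leaf_names() == {"A", "B", "C"}

    def test_determinism(self):
        prots = self._planted_quartet()
        ident = dp.identity_matrix(prots)
        aln = {p.protein_id: p.residues for p in prots}
        t1 = build_nj_tree(ident, alignment=aln, bootstrap=20, seed=9)
        t2 = build_nj_tree(ident, alignment=aln, bootstrap=20, seed=9)
        assert t1.newick == t2.newick

    def test_saturated_distance_capped_with_warning(self):
        m = _matrix(["a", "b", "c"], [("a", "b", 2.0)], default=3.0)
        with pytest.warns(UserWarning, match="capping"):
            gt = build_nj_tree(m)
        assert gt.leaf_names() == {"a", "b", "c"}


class TestCuratePartition:
    def test_monophyletic_labels_unchanged(self):
        gt = _tree("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        part = dp.OGPartition({"a1": "OG1", "a2": "OG1", "b1": "OG2", "b2": "OG2"})
        m = _matrix(["a1", "a2", "b1", "b2"], [("a1", "a2", 95), ("b1", "b2", 95)])
        cur = curate_partition(part, gt, m)
        assert cur.assignment == part.assignment
        assert cur.merged_pairs == []

    def test_interleaved_labels_merged_with_identity_recorded(self):
        gt = _tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        part = dp.OGPartition({"a1": "OG1", "a2": "OG1", "b1": "OG2", "b2": "OG2"})
        m = _matrix(
            ["a1", "a2", "b1", "b2"],
            [("a1", "a2", 95), ("b1", "b2", 95),
             ("a1", "b1", 91), ("a1", "b2", 92), ("a2", "b1", 93), ("a2", "b2", 94)],
        )
        cur = curate_partition(part, gt, m)
        assert len(set(cur.assignment.values())) == 1
        assert cur.merged_pairs == [("OG1", "OG2", 91.0)]

    def test_singleton_inside_clade_absorbed(self):
        gt = _tree("((a1:1,(s1:1,a2:1):1):1,(b1:1,b2:1):1);")
        part = dp.OGPartition(
            {"a1": "OG1", "a2": "OG1", "s1": "A", "b1": "OG2", "b2": "OG2"}
        )
        m = _matrix(
            ["a1", "a2", "s1", "b1", "b2"],
            [("a1", "a2", 95), ("s1", "a1", 92), ("s1", "a2", 92), ("b1", "b2", 95)],
        )
        cur = curate_partition(part, gt, m)
        assert cur.assignment["s1"] == "OG1"
        assert cur.assignment["b1"] == "OG2"
        assert ("A", "OG1", 92.0) in cur.merged_pairs or (
            "OG1", "A", 92.0) in cur.merged_pairs

    def test_no_spurious_merges_on_simulator(self, medium_og):
        assert medium_og["curated"].merged_pairs == []


def test_sister_singleton_not_absorbed():
    # a singleton sister to a clean OG clade stays separate (umbrella
    # territory, not a merge)
    gt = _tree("(((a1:1,a2:1):1,c1:2):1,(b1:1,b2:1):1);")
    part = dp.OGPartition({"a1": "OG1", "a2": "OG1", "c1": "A", "b1": "OG2", "b2": "OG2"})
    m = _matrix(
        ["a1", "a2", "c1", "b1", "b2"],
        [("a1", "a2", 95), ("c1", "a1", 85), ("c1", "a2", 85), ("b1", "b2", 95)],
    )
    cur = curate_partition(part, gt, m)
    assert cur.assignment["c1"] == "A"
    assert cur.merged_pairs == []


class TestDetectUmbrellas:
    def _setup(self, c_ident):
        gt = _tree("(((a1:1,a2:1):1,c1:2):3,(d1:1,d2:1):3);")
        part = dp.OGPartition({"a1": "OG1", "a2": "OG1", "c1": "A", "d1": "OG2", "d2": "OG2"})
        m = _matrix(
            ["a1", "a2", "c1", "d1", "d2"],
            [("a1", "a2", 92), ("c1", "a1", c_ident), ("c1", "a2", c_ident),
             ("d1", "d2", 92)],
            default=40.0,
        )
        return gt, part, m

    def test_umbrella_over_og_and_singleton(self):
        gt, part, m = self._setup(80)
        umb = detect_umbrellas(gt, m, part, floor=75)
        assert len(umb) == 1
        assert umb[0].labels == frozenset({"OG1", "A"})
        assert umb[0].min_identity == 80.0

    def test_floor_excludes_borderline(self):
        gt, part, m = self._setup(74)
        assert detect_umbrellas(gt, m, part, floor=75) == []

    def test_isolated_og_gives_no_umbrella(self):
        gt = _tree("((a1:1,a2:1):1,(d1:1,d2:1):1);")
        part = dp.OGPartition({"a1": "OG1", "a2": "OG1", "d1": "OG2", "d2": "OG2"})
        m = _matrix(["a1", "a2", "d1", "d2"], [("a1", "a2", 92), ("d1", "d2", 92)],
                    default=40.0)
        assert detect_umbrellas(gt, m, part, floor=75) == []


class TestCladeConcordance:
    CLADES = {"gA1": "A", "gA2": "A", "gB1": "B", "gB2": "B"}

    def test_clade_structured_tree_is_vertical(self):
        gt = _tree("((m1:1,m2:1):1,(m3:1,m4:1):1);")
        members = [("m1", "gA1"), ("m2", "gA2"), ("m3", "gB1"), ("m4", "gB2")]
        rep = clade_concordance(members, self.CLADES, gt, og_label="OG1")
        assert rep.verdict == "vertical"
        assert rep.violations == 0

    def test_clade_mixing_flags_hgt(self):
        gt = _tree("((m1:1,m3:1):1,(m2:1,m4:1):1);")
        members = [("m1", "gA1"), ("m2", "gA2"), ("m3", "gB1"), ("m4", "gB2")]
        rep = clade_concordance(members, self.CLADES, gt)
        assert rep.verdict == "hgt_candidate"
        assert rep.violations >= 1

    def test_single_clade_not_applicable(self):
        gt = _tree("((m1:1,m2:1):1,(m3:1,m4:1):1);")
        members = [("m1", "gA1"), ("m2", "gA2")]
        rep = clade_concordance(members, self.CLADES, gt)
        assert rep.verdict == "not_applicable"
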