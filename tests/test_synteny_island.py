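"""RDase cluster detection, synteny links, island delimitation, MGE tallies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dehalopan as dp
from dehalopan.genome_io import Contig, Feature, Genome
from dehalopan.og_classification import IdentityMatrix, OGPartition, UmbrellaGroup
from dehalopan.synteny_island import (
    GenomicIsland,
    compare_islands,
    delimit_island,
    find_rdh_clusters,
    link_clusters,
    mge_tally,
    synteny_conservation,
)


def _feat(fid, start, end, genome="g", contig="c", product="rdhA"):
    return Feature(
        feature_id=fid, genome_id=genome, contig_id=contig,
        start=start, end=end, strand="+", kind="CDS", product=product,
    )


def _features_from_gaps(gaps, length=1000):
    feats = []
    pos = 20001  # away from the contig start so truncation flags stay off
    for i, gap in enumerate([None] + list(gaps)):
        if gap is not None:
            pos += length + gap
        feats.append(_feat(f"r{i}", pos, pos + length - 1))
    return feats


class TestFindRdhClusters:
    def test_gap_9999_joins(self):
        cl = find_rdh_clusters(_features_from_gaps([9999]))
        assert len(cl) == 1 and len(cl[0].members) == 2

    def test_gap_10001_splits(self):
        cl = find_rdh_clusters(_features_from_gaps([10001]))
        assert [len(c.members) for c in cl] == [1, 1]
        assert all(c.isolated for c in cl)

    def test_gap_exactly_10000_joins(self):
        cl = find_rdh_clusters(_features_from_gaps([10000]))
        assert len(cl) == 1

    def test_mixed_gaps(self):
        cl = find_rdh_clusters(_features_from_gaps([5000, 12000]))
        assert [len(c.members) for c in cl] == [2, 1]

    def test_truncation_flags_at_contig_ends(self):
        feats = [_feat("r0", 500, 1500), _feat("r1", 3000, 4000)]
        cl = find_rdh_clusters(feats, contig_lengths={"c": 9000})
        assert len(cl) == 1
        assert cl[0].truncated_start and cl[0].truncated_end

    def test_input_order_invariance(self):
        feats = _features_from_gaps([5000, 12000, 2000])
        shuffled = feats[::-1]
        a = find_rdh_clusters(feats)
        b = find_rdh_clusters(shuffled)
        assert [c.member_ids for c in a] == [c.member_ids for c in b]

    @given(
        st.lists(st.integers(min_value=0, max_value=20000), min_size=0, max_size=8)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_gap_scan(self, gaps):
        feats = _features_from_gaps(gaps)
        got = [c.member_ids for c in find_rdh_clusters(feats)]
        # oracle: linear scan over sorted features
        runs, run = [], [feats[0]]
        for prev, cur in zip(feats, feats[1:]):
            if cur.start - prev.end - 1 <= 10000:
                run.append(cur)
            else:
                runs.append(run)
                run = [cur]
        runs.append(run)
        assert got == [[f.feature_id for f in r] for r in runs]


def _two_clusters():
    a = dp.RdhCluster("g1", "c1", [_feat("a0", 100, 200), _feat("a1", 400, 500)])
    b = dp.RdhCluster("g2", "c1", [_feat("b0", 100, 200), _feat("b1", 400, 500)])
    return a, b


def _ident(pairs, ids):
    n = len(ids)
    m = np.full((n, n), 40.0)
    np.fill_diagonal(m, 100.0)
    idx = {x: i for i, x in enumerate(ids)}
    for x, y, v in pairs:
        m[idx[x], idx[y]] = m[idx[y], idx[x]] = v
    return IdentityMatrix(list(ids), m)


class TestLinkClusters:
    IDS = ["a0", "a1", "b0", "b1"]

    def test_same_og_high_identity_solid(self):
        a, b = _two_clusters()
        part = OGPartition({"a0": "OG1", "b0": "OG1", "a1": "A", "b1": "B"})
        ident = _ident([("a0", "b0", 93)], self.IDS)
        links = link_clusters(a, b, part, [], ident)
        assert len(links) == 1
        assert links[0].tier == "solid" and links[0].identity == 93.0

    def test_umbrella_tier_requires_shared_umbrella(self):
        a, b = _two_clusters()
        part = OGPartition({"a0": "OG1", "b0": "OG2", "a1": "A", "b1": "B"})
        ident = _ident([("a0", "b0", 82)], self.IDS)
        umb = [UmbrellaGroup(frozenset({"OG1", "OG2"}), 80.0, frozenset({"a0", "b0"}))]
        with_umbrella = link_clusters(a, b, part, umb, ident)
        without = link_clusters(a, b, part, [], ident)
        assert [l.tier for l in with_umbrella] == ["umbrella"]
        assert without == []

    def test_tier_identity_bounds_hold(self, island_sim):
        # every emitted link satisfies its tier's bounds by direct lookup
        a, b = _two_clusters()
        part = OGPartition({"a0": "OG1", "b0": "OG1", "a1": "OG2", "b1": "OG2"})
        ident = _ident([("a0", "b0", 91.5), ("a1", "b1", 89.0)], self.IDS)
        links = link_clusters(a, b, part, [], ident)
        for l in links:
            if l.tier == "solid":
                assert l.identity > 90.0
            else:
                assert 75.0 <= l.identity <= 90.0

    def test_best_identity_wins_one_counterpart_each(self):
        a = dp.RdhCluster("g1", "c1", [_feat("a0", 100, 200)])
        b = dp.RdhCluster("g2", "c1", [_feat("b0", 100, 200), _feat("b1", 400, 500)])
        part = OGPartition({"a0": "OG1", "b0": "OG1", "b1": "OG1"})
        ident = _ident([("a0", "b0", 92), ("a0", "b1", 95)], ["a0", "b0", "b1"])
        links = link_clusters(a, b, part, [], ident)
        assert len(links) == 1 and links[0].b_id == "b1"


class TestSyntenyConservation:
    def _links(self, mapping, ident=95.0):
        return [
            dp.SyntenyLink(i, j, f"a{i}", f"b{j}", "solid", ident)
            for i, j in mapping.items()
        ]

    def _cluster(self, gid, n):
        feats = [_feat(f"{gid}{i}", 100 + 1000 * i, 500 + 1000 * i) for i in range(n)]
        return dp.RdhCluster(gid, "c", feats)

    def test_identical_clusters_fully_conserved(self):
        a, b = self._cluster("a", 4), self._cluster("b", 4)
        assert synteny_conservation(a, b, self._links({0: 0, 1: 1, 2: 2, 3: 3})) == 1.0

    def test_internal_deletion_breaks_adjacency(self):
        a, b = self._cluster("a", 4), self._cluster("b", 3)
        # member 1 of a deleted in b: 0->0, 2->1, 3->2
        v = synteny_conservation(a, b, self._links({0: 0, 2: 1, 3: 2}))
        assert v == pytest.approx(1.0)  # the surviving adjacency (2,3) holds
        v2 = synteny_conservation(a, b, self._links({0: 0, 1: 2, 2: 1, 3: 2}))
        assert v2 < 1.0

    def test_reverse_colinear_counts_as_conserved(self):
        a, b = self._cluster("a", 4), self._cluster("b", 4)
        assert synteny_conservation(a, b, self._links({0: 3, 1: 2, 2: 1, 3: 0})) == 1.0

    def test_fewer_than_two_links_undefined(self):
        a, b = self._cluster("a", 3), self._cluster("b", 3)
        assert synteny_conservation(a, b, self._links({0: 0})) is None


class TestDelimitIsland:
    def test_simulator_island_bounds_exact(self, island_sim, island_pipeline):
        truth = {g: (s, e) for g, s, e, _d in island_sim.truth.true_island}
        for g, isl in island_pipeline["islands"].items():
            assert (isl.start, isl.end) == truth[g]
            assert not isl.open_start and not isl.open_end

    def test_island_excludes_flanking_scgs(self, island_pipeline):
        scg_map = island_pipeline["scg_map"]
        for isl in island_pipeline["islands"].values():
            assert isl.upstream_core is not None
            assert isl.downstream_core is not None
            # inner-edge bounds: no single-copy core gene inside the island
            assert all(f.feature_id not in scg_map for f in isl.enclosed)

    def test_query_adjacent_scg_starts_at_inner_edge(self):
        genome = Genome(genome_id="g", contigs=[Contig("c", "ACGT" * 5000)])
        feats = [
            _feat("scg_up", 1000, 2000, product="core"),
            _feat("query", 2001, 2500, product="cargo"),
            _feat("scg_dn", 4000, 5000, product="core"),
        ]
        isl = delimit_island(("c", 2001, 2500), genome, feats,
                             {"scg_up": "GC1", "scg_dn": "GC2"})
        assert isl.start == 2001 and isl.end == 3999
        assert isl.upstream_core == "GC1" and isl.downstream_core == "GC2"

    def test_missing_downstream_scg_open_ended(self):
        genome = Genome(genome_id="g", contigs=[Contig("c", "ACGT" * 3000)])
        feats = [_feat("scg_up", 1000, 2000), _feat("query", 5000, 5500)]
        isl = delimit_island(("c", 5000, 5500), genome, feats, {"scg_up": "GC1"})
        assert isl.open_end and not isl.open_start
        assert isl.end == 12000

    def test_empty_scg_map_rejected(self):
        genome = Genome(genome_id="g", contigs=[Contig("c", "ACGT" * 100)])
        with pytest.raises(ValueError):
            delimit_island(("c", 10, 20), genome, [], {})


class TestCompareIslands:
    def test_identical_islands_single_full_block(self):
        seq = dp.random_genome(77, 12000)
        a = GenomicIsland("g1", "c", 1, len(seq), None, None, sequence=seq)
        b = GenomicIsland("g2", "c", 1, len(seq), None, None, sequence=seq)
        cmp = compare_islands(a, b)
        assert len(cmp.blocks) == 1
        assert cmp.total_shared == len(seq)
        assert cmp.mean_identity == pytest.approx(100.0)

    def test_unrelated_sequences_no_blocks(self):
        a = GenomicIsland("g1", "c", 1, 6000, None, None,
                          sequence=dp.random_genome(1, 6000))
        b = GenomicIsland("g2", "c", 1, 6000, None, None,
                          sequence=dp.random_genome(2, 6000))
        cmp = compare_islands(a, b)
        assert cmp.blocks == []
        assert cmp.mean_identity is None

    def test_planted_identity_recovered(self, island_sim, island_pipeline):
        isls = island_pipeline["islands"]
        donor = next(g for g, _s, _e, d in island_sim.truth.true_island if d)
        recip = next(g for g, _s, _e, d in island_sim.truth.true_island if not d)
        cmp = compare_islands(isls[donor], isls[recip])
        planted = island_sim.truth.island_identity * 100.0
        assert cmp.mean_identity == pytest.approx(planted, abs=0.5)


class TestMGETally:
    def _island(self, products):
        feats = [
            _feat(f"f{i}", 100 * i + 1, 100 * i + 90, product=p)
            for i, p in enumerate(products)
        ]
        return GenomicIsland("g", "c", 1, 10000, None, None, enclosed=feats)

    def test_hand_counted_example(self):
        isl = self._island(
            ["transposase"] * 3 + ["phage integrase"] * 2 + ["hypothetical protein"]
        )
        t = mge_tally(isl)
        assert t.counts == {
            "transposon_is": 3, "conjugative_phage": 2, "other_recombinase": 0
        }
        assert t.n_cds == 6

    def test_no_matches_all_zero(self):
        t = mge_tally(self._island(["hypothetical protein", "ribosomal protein L1"]))
        assert all(v == 0 for v in t.counts.values())

    def test_is_family_keyword(self):
        t = mge_tally(self._island(["IS256 family transposase"]))
        assert t.counts["transposon_is"] == 1
        # bare words containing "is" as letters must not fire the IS rule
        t2 = mge_tally(self._island(["histidine kinase"]))
        assert t2.counts["transposon_is"] == 0

    def test_counts_bounded_by_cds(self, island_pipeline):
        for isl in island_pipeline["islands"].values():
            t = mge_tally(isl)
            assert sum(t.counts.values()) <= t.n_cds
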