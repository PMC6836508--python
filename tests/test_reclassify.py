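"""Adjacency clustering and CNV-type classification."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cnvpost.model import (
    LEFT,
    RIGHT,
    UNKNOWN,
    CNVType,
    GenomicInterval,
    Locus,
)
from cnvpost.reclassify import (
    BELOW_MIN_SIZE,
    INTERCHROM_SINGLETON,
    INVERSION_LIKE,
    ClassificationConfig,
    ExcludedAdjacency,
    classify_cluster,
    classify_singleton,
    cluster_adjacencies,
    reclassify,
)
from cnvpost.model import AdjacencyCluster
from conftest import del_adj, make_adj, random_adjacencies, tdup_adj

CFG = ClassificationConfig()


def brute_force_clusters(adjacencies, window):
    """Independent O(n^2) oracle: pairwise linkage + graph components."""
    g = nx.Graph()
    g.add_nodes_from(range(len(adjacencies)))
    for i, j in itertools.combinations(range(len(adjacencies)), 2):
        a, b = adjacencies[i], adjacencies[j]
        if a.source_tool != b.source_tool:
            continue
        linked = any(
            ba.chrom == bb.chrom and abs(ba.pos - bb.pos) <= window
            for ba in (a.bnd1, a.bnd2)
            for bb in (b.bnd1, b.bnd2)
        )
        if linked:
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestClustering:
    def test_breakpoints_within_window_link(self):
        a = del_adj("chr1", 100, 5000)
        b = tdup_adj("chr1", 4998, 9000)
        clusters = cluster_adjacencies([a, b], CFG)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_window_boundary_is_strict(self):
        a = del_adj("chr1", 100, 5000)
        b = tdup_adj("chr1", 5011, 9000)  # distance 11 > 10
        clusters = cluster_adjacencies([a, b], CFG)
        assert [len(c) for c in clusters] == [1, 1]

    def test_different_tools_never_link(self):
        a = del_adj("chr1", 100, 5000, tool="DELLY")
        b = tdup_adj("chr1", 4998, 9000, tool="MANTA")
        assert len(cluster_adjacencies([a, b], CFG)) == 2

    def test_chromosomes_never_link(self):
        a = del_adj("chr1", 100, 5000)
        b = del_adj("chr2", 100, 5000)
        assert len(cluster_adjacencies([a, b], CFG)) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        adjs = random_adjacencies(rng, int(rng.integers(2, 51)), span=2000)
        clusters = cluster_adjacencies(adjs, CFG)
        index = {id(a): i for i, a in enumerate(adjs)}
        got = {frozenset(index[id(m)] for m in c.members) for c in clusters}
        assert got == brute_force_clusters(adjs, CFG.cluster_window)

    def test_partition_of_input(self, rng):
        adjs = random_adjacencies(rng, 40, span=3000)
        clusters = cluster_adjacencies(adjs, CFG)
        members = [m for c in clusters for m in c.members]
        assert len(members) == len(adjs)
        assert {id(m) for m in members} == {id(a) for a in adjs}


class TestClassifySingleton:
    def test_deletion_signature(self):
        call = classify_singleton(del_adj("chr1", 100, 5000), CFG)
        assert call.cnv_type is CNVType.DEL
        assert call.region == GenomicInterval("chr1", 100, 5000)
        assert call.size == 4900

    def test_tandem_duplication_signature(self):
        call = classify_singleton(tdup_adj("chr1", 100, 5000), CFG)
        assert call.cnv_type is CNVType.TDUP
        assert call.region == GenomicInterval("chr1", 100, 5000)

    def test_small_event_excluded_by_min_size(self):
        result = classify_singleton(del_adj("chr1", 100, 130), CFG)
        assert isinstance(result, ExcludedAdjacency)
        assert result.reason == BELOW_MIN_SIZE

    def test_min_size_boundary_inclusive(self):
        call = classify_singleton(del_adj("chr1", 100, 150), CFG)
        assert call.cnv_type is CNVType.DEL  # exactly 50 bp passes

    def test_insertion_with_sequence(self):
        seq = "A" * 80
        call = classify_singleton(
            make_adj("chr1", 500, RIGHT, "chr1", 500, LEFT, ins=seq), CFG
        )
        assert call.cnv_type is CNVType.INS
        assert call.insertion_point == Locus("chr1", 500)
        assert call.size == 80

    def test_unresolved_insertion_within_tolerance(self):
        call = classify_singleton(
            make_adj("chr1", 500, RIGHT, "chr1", 508, LEFT, ins=UNKNOWN), CFG
        )
        assert call.cnv_type is CNVType.INS
        assert call.size is UNKNOWN

    def test_inversion_like_excluded(self):
        result = classify_singleton(
            make_adj("chr1", 100, RIGHT, "chr1", 5000, RIGHT), CFG
        )
        assert result.reason == INVERSION_LIKE

    def test_interchromosomal_singleton_excluded(self):
        result = classify_singleton(
            make_adj("chr1", 100, RIGHT, "chr2", 5000, LEFT), CFG
        )
        assert result.reason == INTERCHROM_SINGLETON


class TestDispersedDuplication:
    def test_downstream_copy_recovered_from_del_tdup_pair(self):
        """The canonical mis-call: a copy of [10000, 12000) inserted at
        50000 imprints a tandem-duplication-like and a deletion-like
        adjacency sharing the insertion breakpoint."""
        t = tdup_adj("chr1", 10000, 50000, id="t")
        d = del_adj("chr1", 12000, 50001, id="d")
        calls, excluded = classify_cluster(AdjacencyCluster([t, d]), CFG)
        assert [c.cnv_type for c in calls] == [CNVType.DDUP]
        call = calls[0]
        assert call.region == GenomicInterval("chr1", 10000, 12000)
        assert call.insertion_point == Locus("chr1", 50000)
        assert excluded == []

    def test_upstream_copy_signature(self):
        # copy of [30000, 32000) inserted at 5000 (upstream of template)
        d = del_adj("chr1", 5000, 30000)
        t = tdup_adj("chr1", 5001, 32000)
        calls, _ = classify_cluster(AdjacencyCluster([d, t]), CFG)
        (call,) = calls
        assert call.cnv_type is CNVType.DDUP
        assert call.region == GenomicInterval("chr1", 30000, 32000)
        assert call.insertion_point == Locus("chr1", 5000)

    def test_distant_breakpoints_stay_del_plus_tdup(self):
        t = tdup_adj("chr1", 10000, 50000)
        d = del_adj("chr1", 12000, 50040)  # 40 bp apart: no shared breakpoint
        result = reclassify([t, d], CFG)
        assert sorted(c.cnv_type.value for c in result.calls) == ["DEL", "TDUP"]

    def test_interchromosomal_pair(self):
        # copy of chr2:[7000, 9000) inserted at chr5:3000
        j_in = make_adj("chr2", 7000, LEFT, "chr5", 3000, RIGHT)
        j_out = make_adj("chr2", 9000, RIGHT, "chr5", 3000, LEFT)
        calls, _ = classify_cluster(AdjacencyCluster([j_in, j_out]), CFG)
        (call,) = calls
        assert call.cnv_type is CNVType.DDUP
        assert call.region == GenomicInterval("chr2", 7000, 9000)
        assert call.insertion_point.chrom == "chr5"

    def test_support_is_per_signal_minimum(self):
        t = tdup_adj("chr1", 10000, 50000, pe=8, sr=2)
        d = del_adj("chr1", 12000, 50000, pe=3, sr=9)
        (call,), _ = classify_cluster(AdjacencyCluster([t, d]), CFG)
        assert (call.pe_support, call.sr_support) == (3, 2)

    def test_tiny_template_consumed_not_reinterpreted(self):
        """A recognized dispersed-duplication pair with a sub-threshold
        template is excluded whole, never resurrected as DEL + TDUP."""
        t = tdup_adj("chr1", 10000, 50000)
        d = del_adj("chr1", 10030, 50000)  # template 30 bp < 50
        calls, excluded = classify_cluster(AdjacencyCluster([t, d]), CFG)
        assert calls == []
        assert sorted(e.reason for e in excluded) == [BELOW_MIN_SIZE] * 2

    def test_inverted_signature_gated_by_flag(self):
        rr = make_adj("chr1", 12000, RIGHT, "chr1", 50000, RIGHT)
        ll = make_adj("chr1", 10000, LEFT, "chr1", 50001, LEFT)
        calls, excluded = classify_cluster(AdjacencyCluster([rr, ll]), CFG)
        assert calls == []
        assert {e.reason for e in excluded} == {INVERSION_LIKE}
        cfg = ClassificationConfig(allow_inverted_ddup=True)
        calls, _ = classify_cluster(AdjacencyCluster([rr, ll]), cfg)
        assert [c.cnv_type for c in calls] == [CNVType.DDUP]
        assert calls[0].region == GenomicInterval("chr1", 10000, 12000)


class TestReclassify:
    def test_singleton_ddup_adjacency_falls_back(self):
        """With only one of the two adjacencies detected, the survivor is
        reported as the deletion or tandem duplication it spells."""
        only_del = reclassify([del_adj("chr1", 12000, 50000)], CFG)
        assert [c.cnv_type for c in only_del.calls] == [CNVType.DEL]
        only_tdup = reclassify([tdup_adj("chr1", 10000, 50000)], CFG)
        assert [c.cnv_type for c in only_tdup.calls] == [CNVType.TDUP]

    def test_empty_input(self):
        result = reclassify([], CFG)
        assert result.calls == [] and result.excluded == []

    def test_partition_property(self, rng):
        adjs = random_adjacencies(rng, 80, span=100_000)
        result = reclassify(adjs, CFG)
        n_in_calls = sum(len(c.adjacencies) for c in result.calls)
        assert n_in_calls + len(result.excluded) == len(adjs)

    def test_no_call_below_min_size(self, rng):
        adjs = random_adjacencies(rng, 120, span=4000)
        result = reclassify(adjs, CFG)
        for call in result.calls:
            assert call.size is UNKNOWN or call.size >= CFG.min_size

    def test_deterministic_order(self, rng):
        adjs = random_adjacencies(rng, 60, span=50_000)
        r1 = reclassify(list(adjs), CFG)
        r2 = reclassify(list(reversed(adjs)), CFG)
        assert r1.calls == r2.calls
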