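"""Motif attachment, share edges, rankings and frequency tables."""

import random

import pytest

from netenhance import (
    MotifAssignment,
    NodeRecord,
    attach_motifs,
    build_network,
    motif_frequency_table,
    motif_share_edges,
    top_shared_motifs,
)
from netenhance._bruteforce import rank_family_motifs, shared_motif_pairs
from netenhance.motif_mapping import pie_slices, round_half_up

from conftest import random_network


def assign(c, m, overlap=0.5, prob=0.5):
    return MotifAssignment(cluster_id=c, motif_id=m, probability=prob, overlap=overlap)


class TestAttach:
    def test_pie_remainder_below_one(self):
        slices = pie_slices([("m1", 0.6), ("m2", 0.3)])
        assert slices == [("m1", 0.6), ("m2", 0.3), ("remainder", pytest.approx(0.1))]

    def test_pie_rescaled_above_one(self):
        slices = pie_slices([("m1", 0.8), ("m2", 0.8)])
        assert slices == [("m1", 0.5), ("m2", 0.5)]

    def test_node_without_motifs_gets_full_remainder(self, toy_network):
        attach_motifs(toy_network, [])
        node = toy_network.nodes[1]
        assert node.extra_attributes["motifs"] == []
        assert node.extra_attributes["pie"] == [("remainder", 1.0)]

    def test_unknown_cluster_ids_skipped(self, toy_network, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            attach_motifs(toy_network, [assign(999, "m1")])
        assert "skipped 1" in caplog.text

    def test_motifs_sorted_by_overlap_descending(self, toy_network):
        attach_motifs(toy_network, [assign(1, "m1", 0.3), assign(1, "m2", 0.6)])
        assert toy_network.nodes[1].extra_attributes["motifs"] == \
            [("m2", 0.6), ("m1", 0.3)]


class TestShareEdges:
    def test_cosine_pair_sharing_two_motifs_gets_two_edges(self, toy_network):
        edges = motif_share_edges(
            toy_network,
            [assign(1, "m1"), assign(2, "m1"), assign(1, "m2"), assign(2, "m2")])
        assert [(e.id_a, e.id_b, e.motif_id) for e in edges] == \
            [(1, 2, "m1"), (1, 2, "m2")]
        assert len(toy_network.edges) == 4  # cosine edges untouched

    def test_all_pairs_connects_unlinked_triangle(self):
        nodes = [NodeRecord(cluster_id=c) for c in (1, 2, 3)]
        net = build_network(nodes, [])
        edges = motif_share_edges(net, [assign(c, "m1") for c in (1, 2, 3)],
                                  scope="all_pairs", max_motif_frequency=10)
        assert [(e.id_a, e.id_b) for e in edges] == [(1, 2), (1, 3), (2, 3)]

    def test_frequency_guard_skips_ubiquitous_motifs(self):
        nodes = [NodeRecord(cluster_id=c) for c in range(1, 6)]
        net = build_network(nodes, [])
        edges = motif_share_edges(net, [assign(c, "m1") for c in range(1, 6)],
                                  scope="all_pairs", max_motif_frequency=4)
        assert edges == []

    @pytest.mark.parametrize("scope", ["cosine_pairs", "all_pairs"])
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_pairwise_intersection_oracle(self, scope, seed):
        rng = random.Random(seed)
        nodes, cos_edges = random_network(rng, n_max=15)
        net = build_network(nodes, cos_edges)
        motifs = ["m1", "m2", "m3"]
        assignments = []
        node_motifs = {}
        for n in nodes:
            chosen = set(rng.sample(motifs, rng.randrange(0, 4)))
            node_motifs[n.cluster_id] = chosen
            assignments.extend(assign(n.cluster_id, m) for m in sorted(chosen))
        if scope == "cosine_pairs":
            expected = shared_motif_pairs(node_motifs,
                                          pairs=sorted(net.cosine_pairs()))
            got = motif_share_edges(net, assignments, scope="cosine_pairs")
        else:
            expected = shared_motif_pairs(node_motifs, max_motif_frequency=5)
            got = motif_share_edges(net, assignments, scope="all_pairs",
                                    max_motif_frequency=5)
        assert {(e.id_a, e.id_b, e.motif_id) for e in got} == expected
        # every endpoint carries the named motif
        for e in got:
            assert e.motif_id in node_motifs[e.id_a]
            assert e.motif_id in node_motifs[e.id_b]


class TestTopShared:
    def test_ranked_by_member_count(self, toy_network):
        assignments = ([assign(c, "m1") for c in (1, 2, 3)]
                       + [assign(c, "m2") for c in (1, 2)])
        top = top_shared_motifs(toy_network, assignments, x=1)
        assert top[1] == [("m1", 3)]

    def test_overlap_sum_ranking_can_reorder(self, toy_network):
        # m1 on 2 nodes with tiny overlaps; m2 on 1 node with a big one
        assignments = [assign(1, "m1", 0.31), assign(2, "m1", 0.31),
                       assign(1, "m2", 0.9)]
        by_nodes = top_shared_motifs(toy_network, assignments, x=1)
        by_overlap = top_shared_motifs(toy_network, assignments, x=1,
                                       rank_by="overlap_sum")
        assert by_nodes[1] == [("m1", 2)]
        assert by_overlap[1] == [("m2", 1)]

    def test_x_larger_than_motif_count_gives_full_list(self, toy_network):
        top = top_shared_motifs(toy_network, [assign(1, "m1")], x=99)
        assert top[1] == [("m1", 1)]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_count_and_sort_oracle(self, seed):
        rng = random.Random(seed)
        nodes, cos_edges = random_network(rng, n_max=12)
        net = build_network(nodes, cos_edges)
        assignments = []
        node_motifs = {n.cluster_id: set() for n in nodes}
        for n in nodes:
            for m in rng.sample(["m1", "m2", "m3", "m4"], rng.randrange(0, 5)):
                node_motifs[n.cluster_id].add(m)
                assignments.append(assign(n.cluster_id, m))
        x = rng.randrange(1, 5)
        top = top_shared_motifs(net, assignments, x=x)
        for fid, members in net.families.items():
            expected = rank_family_motifs(
                {c: node_motifs[c] for c in members}, x)
            assert top[fid] == expected


class TestFrequencies:
    @pytest.mark.parametrize("count,decimals,expected", [
        (478, 1, 7.7), (231, 1, 3.7), (28, 2, 0.45), (1500, 0, 24.0),
        (110, 1, 1.8), (186, 1, 3.0),
    ])
    def test_printed_percentages_reproduced(self, count, decimals, expected):
        nodes = [NodeRecord(cluster_id=c) for c in range(1, 6229)]
        net = build_network(nodes, [])
        assignments = [assign(c, "m1") for c in range(1, count + 1)]
        (freq,) = motif_frequency_table(net, assignments, decimals=decimals)
        assert freq.n_nodes_with_motif == count
        assert freq.percent_of_nodes == expected

    def test_absent_motif_has_no_row(self, toy_network):
        assert motif_frequency_table(toy_network, []) == []

    def test_half_up_rounding(self):
        assert round_half_up(2.5, 0) == 3.0
        assert round_half_up(0.445, 2) == 0.45
        assert round_half_up(7.6499, 1) == 7.6

    def test_determinism_and_bounds(self, bundle):
        from netenhance import filter_assignments, read_edge_table, read_motif_table, read_node_table

        out, manifest = bundle
        net = build_network(read_node_table(out / "nodes.tsv"),
                            read_edge_table(out / "edges.tsv"))
        kept = filter_assignments(read_motif_table(out / "motifs.tsv"))
        t1 = motif_frequency_table(net, kept)
        t2 = motif_frequency_table(net, kept)
        assert t1 == t2
        annotated = {a.cluster_id for a in kept}
        assert sum(f.n_nodes_with_motif for f in t1) >= len(annotated)
        for f in t1:
            assert f.n_nodes_with_motif <= net.n_nodes
            gt = manifest["motif_frequencies"][f.motif_id]
            assert (f.n_nodes_with_motif, f.percent_of_nodes) == \
                (gt["n_nodes"], gt["percent"])
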