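"""Mapping substructure motifs onto the molecular network.

Filtered motif assignments are attached to nodes (with pie-chart slice
sizes taken from the overlap scores), drawn as extra edges between nodes
sharing a motif, ranked per family ("the x most shared motifs"), and
summarised network-wide as frequency counts and percentages.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd

from .model import (
    MolecularNetwork,
    MotifAssignment,
    MotifEdge,
    MotifFrequency,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_MOTIF_FREQUENCY = 50

#: node attribute name carrying the ordered motif list
MOTIF_ATTR = "motifs"


def _node_motifs(network: MolecularNetwork,
                 assignments: Sequence[MotifAssignment],
                 ) -> tuple[dict[int, list[tuple[str, float]]], int]:
    """Per-node [(motif, overlap)] sorted by overlap desc then motif id;
    returns also the count of assignments referencing unknown nodes."""
    per_node: dict[int, list[tuple[str, float]]] = defaultdict(list)
    n_unknown = 0
    for a in assignments:
        if a.cluster_id not in network.nodes:
            n_unknown += 1
            continue
        per_node[a.cluster_id].append((a.motif_id, a.overlap))
    for cid in per_node:
        per_node[cid].sort(key=lambda mo: (-mo[1], mo[0]))
    return per_node, n_unknown


def attach_motifs(network: MolecularNetwork,
                  assignments: Sequence[MotifAssignment]) -> MolecularNetwork:
    """Attach motif attributes to nodes (in place; network returned).

    Each node gains ``extra_attributes["motifs"]`` = list of (motif_id,
    overlap) sorted by overlap descending, plus ``pie`` — the pie-chart
    slices: the raw overlap values with a trailing remainder slice when they
    sum below 1, or proportionally rescaled to 1 when they sum above it.
    Assignments naming unknown cluster ids are skipped with a logged count.
    """
    per_node, n_unknown = _node_motifs(network, assignments)
    if n_unknown:
        logger.warning("skipped %d motif assignment(s) for unknown nodes", n_unknown)
    for cid, node in network.nodes.items():
        motifs = per_node.get(cid, [])
        node.extra_attributes[MOTIF_ATTR] = motifs
        node.extra_attributes["pie"] = pie_slices(motifs)
    return network


def pie_slices(motifs: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Pie-chart slices for one node's motifs.

    Slices carry the raw overlap scores; a ``(remainder, r)`` slice fills the
    gap to 1 when the overlaps sum below 1, and slices are rescaled
    proportionally when they sum above 1.
    """
    total = sum(o for _, o in motifs)
    if total > 1.0:
        return [(m, o / total) for m, o in motifs]
    slices = [(m, o) for m, o in motifs]
    if total < 1.0:
        slices.append(("remainder", 1.0 - total))
    return slices


def motif_share_edges(network: MolecularNetwork,
                      assignments: Sequence[MotifAssignment],
                      scope: str = "cosine_pairs",
                      max_motif_frequency: Optional[int] = DEFAULT_MAX_MOTIF_FREQUENCY,
                      ) -> list[MotifEdge]:
    """Edges between node pairs sharing a motif.

    ``scope="cosine_pairs"`` draws motif edges only along existing cosine
    edges (the family topology); ``"all_pairs"`` connects every node pair
    sharing a motif, restricted to motifs present on at most
    ``max_motif_frequency`` nodes to keep ubiquitous motifs from exploding
    quadratically.  Output is sorted (id_a, id_b, motif_id).
    """
    if scope not in ("cosine_pairs", "all_pairs"):
        raise ValueError(f"unknown scope {scope!r}")
    per_node, _ = _node_motifs(network, assignments)
    motif_sets = {cid: {m for m, _ in motifs} for cid, motifs in per_node.items()}

    edges: set[MotifEdge] = set()
    if scope == "cosine_pairs":
        for (a, b) in network.cosine_pairs():
            shared = motif_sets.get(a, set()) & motif_sets.get(b, set())
            for m in shared:
                edges.add(MotifEdge(id_a=a, id_b=b, motif_id=m))
    else:
        nodes_per_motif: dict[str, set[int]] = defaultdict(set)
        for cid, motifs in motif_sets.items():
            for m in motifs:
                nodes_per_motif[m].add(cid)
        for m, members in nodes_per_motif.items():
            if max_motif_frequency is not None and len(members) > max_motif_frequency:
                logger.info("motif %s on %d nodes exceeds max frequency %d; skipped",
                            m, len(members), max_motif_frequency)
                continue
            for a, b in combinations(sorted(members), 2):
                edges.add(MotifEdge(id_a=a, id_b=b, motif_id=m))
    return sorted(edges, key=lambda e: (e.id_a, e.id_b, e.motif_id))


def top_shared_motifs(network: MolecularNetwork,
                      assignments: Sequence[MotifAssignment],
                      x: int = 5, rank_by: str = "nodes") -> dict:
    """The x most shared motifs per family.

    A motif's share within a family is the number of member nodes carrying
    it (``rank_by="nodes"``, the default) or the summed overlap across
    members (``rank_by="overlap_sum"``); ranking is descending, ties by
    motif id.  Returns {family_id: [(motif_id, n_member_nodes), ...]}
    truncated to x — the count reported is always the node count.
    """
    if x < 1:
        raise ValueError(f"x must be >= 1, got {x}")
    if rank_by not in ("nodes", "overlap_sum"):
        raise ValueError(f"unknown ranking {rank_by!r}")
    per_node, _ = _node_motifs(network, assignments)
    out = {}
    for fid, members in network.families.items():
        counts: dict[str, int] = defaultdict(int)
        overlap_sum: dict[str, float] = defaultdict(float)
        for cid in members:
            for m, o in per_node.get(cid, []):
                counts[m] += 1
                overlap_sum[m] += o
        if rank_by == "nodes":
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        else:
            ranked = sorted(counts.items(),
                            key=lambda kv: (-overlap_sum[kv[0]], kv[0]))
        out[fid] = ranked[:x]
    return out


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (2.5 -> 3 at 0 decimals), as used for the
    printed motif percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def motif_frequency_table(network: MolecularNetwork,
                          assignments: Sequence[MotifAssignment],
                          decimals: int = 1) -> list[MotifFrequency]:
    """Network-wide motif frequencies.

    One row per motif: the number of distinct nodes carrying it and that
    count as a half-up-rounded percentage of all network nodes.
    """
    per_node, _ = _node_motifs(network, assignments)
    nodes_per_motif: dict[str, set[int]] = defaultdict(set)
    for cid, motifs in per_node.items():
        for m, _ in motifs:
            nodes_per_motif[m].add(cid)
    total = network.n_nodes
    out = []
    for m in sorted(nodes_per_motif):
        n = len(nodes_per_motif[m])
        pct = round_half_up(100.0 * n / total, decimals) if total else 0.0
        out.append(MotifFrequency(motif_id=m, n_nodes_with_motif=n,
                                  percent_of_nodes=pct))
    return out


def motif_frequency_frame(freqs: Sequence[MotifFrequency]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"motif_id": f.motif_id, "n_nodes_with_motif": f.n_nodes_with_motif,
          "percent_of_nodes": f.percent_of_nodes} for f in freqs],
        columns=["motif_id", "n_nodes_with_motif", "percent_of_nodes"],
    )
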