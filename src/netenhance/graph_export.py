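"""Serialization of the enhanced network and the summary tables.

The enhanced graphml carries, per node: the core fields, the family's
consensus class and score at each ontology level, and the motif list (as a
delimited string plus one numeric overlap attribute per motif).  Cosine and
motif edges live side by side as a multigraph, distinguished by the
``edge_kind`` attribute, with stable ids ``c<N>`` / ``m<N>`` assigned in
sorted order so identical inputs always serialize to identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .model import (
    MolecularNetwork,
    MotifEdge,
    MotifFrequency,
)
from .motif_mapping import MOTIF_ATTR, motif_frequency_frame

#: delimiter for the serialized per-node motif list
_MOTIF_LIST_SEP = ";"


@dataclass
class EnhancedNetwork:
    """A molecular network plus its annotation layers, ready for export."""

    base: MolecularNetwork
    node_classes: dict = field(default_factory=dict)  # cluster_id -> {attr: value}
    motif_edges: list[MotifEdge] = field(default_factory=list)


def _node_attributes(enh: EnhancedNetwork, cluster_id: int) -> dict:
    node = enh.base.nodes[cluster_id]
    attrs: dict = {"family_id": int(node.family_id)}
    if node.precursor_mz is not None:
        attrs["precursor_mz"] = float(node.precursor_mz)
    if node.parent_mass is not None:
        attrs["parent_mass"] = float(node.parent_mass)
    for key, value in sorted(node.extra_attributes.items()):
        if key in (MOTIF_ATTR, "pie"):
            continue
        attrs[key] = value
    motifs = node.extra_attributes.get(MOTIF_ATTR, [])
    attrs[MOTIF_ATTR] = _MOTIF_LIST_SEP.join(m for m, _ in motifs)
    for m, overlap in motifs:
        attrs[f"motif:{m}"] = float(overlap)
    for key, value in sorted(enh.node_classes.get(cluster_id, {}).items()):
        attrs[f"cf:{key}"] = value
    return attrs


def to_multigraph(enh: EnhancedNetwork) -> nx.MultiGraph:
    """Canonically ordered multigraph: nodes by cluster id, cosine edges
    sorted before motif edges, edge ids c1..cN / m1..mN."""
    g = nx.MultiGraph()
    for cid in sorted(enh.base.nodes):
        g.add_node(cid, **_node_attributes(enh, cid))
    cosine_sorted = sorted(enh.base.edges,
                           key=lambda e: (e.pair, -(e.cosine if e.cosine is not None
                                                    else -1.0)))
    for i, e in enumerate(cosine_sorted, start=1):
        attrs = {"edge_kind": "cosine"}
        if e.cosine is not None:
            attrs["cosine"] = float(e.cosine)
        g.add_edge(*e.pair, key=f"c{i}", **attrs)
    motif_sorted = sorted(enh.motif_edges,
                          key=lambda e: (e.id_a, e.id_b, e.motif_id))
    for i, e in enumerate(motif_sorted, start=1):
        g.add_edge(e.id_a, e.id_b, key=f"m{i}",
                   edge_kind="motif", motif_id=e.motif_id)
    return g


def write_enhanced_graphml(enh: EnhancedNetwork, path) -> None:
    """Write the enhanced network; byte-stable for identical inputs and
    re-readable by ``io_network.read_graphml`` with full fidelity."""
    nx.write_graphml(to_multigraph(enh), path)


def enhanced_from_network(network: MolecularNetwork) -> EnhancedNetwork:
    """Wrap a network read back from graphml for re-serialization.

    Class attributes previously written under the ``cf:`` prefix are routed
    back into the class layer so a write -> read -> write cycle reproduces
    the original bytes.
    """
    node_classes: dict = {}
    for cid, node in network.nodes.items():
        cf = {k[3:]: v for k, v in node.extra_attributes.items()
              if k.startswith("cf:")}
        if cf:
            node_classes[cid] = cf
        motif_names = node.extra_attributes.get(MOTIF_ATTR, "")
        if isinstance(motif_names, str):
            motifs = []
            for m in motif_names.split(_MOTIF_LIST_SEP):
                if m:
                    motifs.append((m, float(node.extra_attributes[f"motif:{m}"])))
            node.extra_attributes[MOTIF_ATTR] = motifs
        node.extra_attributes = {
            k: v for k, v in node.extra_attributes.items()
            if not k.startswith(("cf:", "motif:"))
        }
    return EnhancedNetwork(base=network, node_classes=node_classes,
                           motif_edges=list(network.motif_edges))


def classification_frame(table: pd.DataFrame) -> pd.DataFrame:
    return table


def write_summary_tables(classification_table: pd.DataFrame,
                         motif_frequencies: Sequence[MotifFrequency],
                         top_motifs: Mapping,
                         path_prefix: str) -> list[str]:
    """Write the three tab-separated summaries.

    ``<prefix>_family_classes.tsv`` — family_id, level, top_class, score,
    n_nodes, n_annotated; ``<prefix>_motif_frequencies.tsv`` — motif_id,
    n_nodes_with_motif, percent_of_nodes; ``<prefix>_top_motifs.tsv`` —
    family_id, rank, motif_id, n_member_nodes.  Returns the paths written.
    """
    paths = []

    p = f"{path_prefix}_family_classes.tsv"
    classification_table.to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = f"{path_prefix}_motif_frequencies.tsv"
    motif_frequency_frame(motif_frequencies).to_csv(p, sep="\t", index=False)
    paths.append(p)

    rows = []
    from .model import sorted_family_ids

    for fid in sorted_family_ids(top_motifs):
        for rank, (motif_id, n) in enumerate(top_motifs[fid], start=1):
            rows.append({"family_id": fid, "rank": rank,
                         "motif_id": motif_id, "n_member_nodes": n})
    p = f"{path_prefix}_top_motifs.tsv"
    pd.DataFrame(rows, columns=["family_id", "rank", "motif_id",
                                "n_member_nodes"]).to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths
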