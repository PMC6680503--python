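"""Readers and builders for the molecular-network side of the inputs.

Edge and node tables come from a molecular-networking job (tab-separated,
header row); graphml comes either from the same platform or from a previous
run of this package.  Families (molecular families, MFs) are connected
components of the cosine-similarity graph; they can be recomputed here or
trusted from the export's component-index column.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .dialects import Dialect, SIMPLE_NETWORK
from .model import (
    SINGLETON,
    CosineEdge,
    MolecularNetwork,
    MotifEdge,
    NetworkFormatError,
    NetworkValidationError,
    NodeRecord,
)

logger = logging.getLogger(__name__)

#: Node-table columns mapped onto dedicated NodeRecord fields.
_CORE_NODE_FIELDS = ("cluster_id", "precursor_mz", "parent_mass", "family_id")


def _require_columns(df: pd.DataFrame, dialect: Dialect, fields: Iterable[str],
                     path) -> None:
    missing = [dialect.column(f) for f in fields if dialect.column(f) not in df.columns]
    if missing:
        raise NetworkFormatError(
            f"{path}: missing required column(s) {missing} "
            f"(dialect {dialect.name!r})"
        )


def read_edge_table(path, dialect: Dialect = SIMPLE_NETWORK) -> list[CosineEdge]:
    """Read a cosine-edge table; self-loops are dropped (count logged)."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    _require_columns(df, dialect, ("id_a", "id_b", "cosine"), path)
    col_a, col_b = dialect.column("id_a"), dialect.column("id_b")
    col_c = dialect.column("cosine")

    edges: list[CosineEdge] = []
    n_self = 0
    for pos, (_, row) in enumerate(df.iterrows()):
        i = pos + 2  # header occupies line 1
        try:
            a, b = int(row[col_a]), int(row[col_b])
        except (TypeError, ValueError) as exc:
            raise NetworkFormatError(f"{path}, line {i}: non-integer node id") from exc
        raw_c = row[col_c]
        try:
            cosine = None if pd.isna(raw_c) else float(raw_c)
        except (TypeError, ValueError) as exc:
            raise NetworkFormatError(
                f"{path}, line {i}: non-numeric cosine {raw_c!r}"
            ) from exc
        if a == b:
            n_self += 1
            continue
        edges.append(CosineEdge(id_a=a, id_b=b, cosine=cosine))
    if n_self:
        logger.info("%s: dropped %d self-loop edge(s)", path, n_self)
    return edges


def read_node_table(path, dialect: Dialect = SIMPLE_NETWORK) -> list[NodeRecord]:
    """Read a node table; unmapped columns are kept in ``extra_attributes``."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    _require_columns(df, dialect, ("cluster_id",), path)
    col_id = dialect.column("cluster_id")
    mapped = {dialect.column(f): f for f in _CORE_NODE_FIELDS if dialect.has(f)}

    ids = df[col_id].astype(int)
    dupes = sorted(int(x) for x in ids[ids.duplicated()].unique())
    if dupes:
        raise NetworkValidationError(f"{path}: duplicate cluster id(s) {dupes}")

    records: list[NodeRecord] = []
    for _, row in df.iterrows():
        extra = {c: row[c] for c in df.columns if c not in mapped and pd.notna(row[c])}

        def _opt_float(field: str) -> Optional[float]:
            if not dialect.has(field):
                return None
            col = dialect.column(field)
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        family = SINGLETON
        if dialect.has("family_id"):
            col = dialect.column("family_id")
            if col in df.columns and pd.notna(row[col]):
                family = int(row[col])
        records.append(
            NodeRecord(
                cluster_id=int(row[col_id]),
                precursor_mz=_opt_float("precursor_mz"),
                parent_mass=_opt_float("parent_mass"),
                family_id=family,
                extra_attributes=extra,
            )
        )
    return records


def _connected_components(node_ids: set[int],
                          edges: list[CosineEdge]) -> list[frozenset[int]]:
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    g.add_edges_from((e.id_a, e.id_b) for e in edges)
    return [frozenset(c) for c in nx.connected_components(g)]


def _number_families(components: list[frozenset[int]]):
    """Deterministic family keys: multi-member components ordered by smallest
    member id and numbered from 1; singletons keyed ``"S<cluster_id>"``."""
    multi = sorted((c for c in components if len(c) > 1), key=min)
    families: dict = {i: c for i, c in enumerate(multi, start=1)}
    for c in components:
        if len(c) == 1:
            (cid,) = c
            families[f"S{cid}"] = c
    return families


def build_network(nodes: list[NodeRecord], edges: list[CosineEdge],
                  family_source: str = "recompute") -> MolecularNetwork:
    """Assemble a validated network and its family partition.

    ``family_source="recompute"`` derives families from cosine-graph
    connectivity; ``"trust_column"`` keeps the export's family column but
    validates it against connectivity and logs any mismatch.
    """
    if family_source not in ("recompute", "trust_column"):
        raise ValueError(f"unknown family_source {family_source!r}")
    node_map = {n.cluster_id: n for n in nodes}
    if len(node_map) != len(nodes):
        raise NetworkValidationError("duplicate cluster ids in node list")
    for e in edges:
        if e.id_a not in node_map or e.id_b not in node_map:
            raise NetworkValidationError(
                f"edge {e.id_a}-{e.id_b} references unknown node"
            )

    components = _connected_components(set(node_map), edges)
    families = _number_families(components)

    if family_source == "trust_column":
        # exported family column must agree with connectivity
        n_mismatch = 0
        for fid, members in families.items():
            declared = {node_map[c].family_id for c in members}
            if len(members) == 1:
                continue
            if len(declared) > 1 or SINGLETON in declared:
                n_mismatch += 1
                logger.warning(
                    "family %r (members %s) has inconsistent declared ids %s",
                    fid, sorted(members), sorted(declared),
                )
        if n_mismatch:
            logger.warning("%d families mismatch the declared family column",
                           n_mismatch)
        # keep declared numbering where it is consistent
        renamed: dict = {}
        for fid, members in families.items():
            if len(members) == 1:
                renamed[fid] = members
                continue
            declared = {node_map[c].family_id for c in members}
            did = declared.pop() if len(declared) == 1 else None
            if did is None or did == SINGLETON or did in renamed:
                did = fid
            while did in renamed:  # collision with an already-claimed id
                did += 1000000
            renamed[did] = members
        families = renamed

    for fid, members in families.items():
        for cid in members:
            node_map[cid].family_id = SINGLETON if len(members) == 1 else int(fid)

    return MolecularNetwork(nodes=node_map, edges=list(edges), families=families)


def read_graphml(path) -> MolecularNetwork:
    """Read a network (plain or enhanced) from graphml.

    Cosine and motif edges are told apart by the ``edge_kind`` attribute;
    edges without a cosine attribute load with cosine marked absent.  Node
    annotations beyond the core fields land in ``extra_attributes``.
    """
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # nx raises lxml/xml parse errors verbatim
        raise NetworkFormatError(f"{path}: malformed graphml: {exc}") from exc

    nodes: list[NodeRecord] = []
    for nid, data in g.nodes(data=True):
        data = dict(data)
        rec = NodeRecord(
            cluster_id=int(nid),
            precursor_mz=data.pop("precursor_mz", None),
            parent_mass=data.pop("parent_mass", None),
            family_id=int(data.pop("family_id", SINGLETON)),
            extra_attributes=data,
        )
        nodes.append(rec)

    cosine_edges: list[CosineEdge] = []
    motif_edges: list[MotifEdge] = []
    if g.is_multigraph():
        edge_iter = ((u, v, d) for u, v, _, d in g.edges(keys=True, data=True))
    else:
        edge_iter = g.edges(data=True)
    for u, v, data in edge_iter:
        kind = data.get("edge_kind", "cosine")
        a, b = int(u), int(v)
        if kind == "motif":
            lo, hi = min(a, b), max(a, b)
            motif_edges.append(MotifEdge(id_a=lo, id_b=hi, motif_id=data["motif_id"]))
        else:
            cosine = data.get("cosine")
            cosine_edges.append(
                CosineEdge(id_a=a, id_b=b,
                           cosine=None if cosine is None else float(cosine))
            )

    net = build_network(nodes, cosine_edges, family_source="recompute")
    net.motif_edges = motif_edges
    return net
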