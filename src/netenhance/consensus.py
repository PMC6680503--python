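"""Per-family consensus chemical class and classification score.

For every molecular family and every ontology level, each annotated member
node splits one unit of vote mass equally over the chemical classes of its
candidate structures (a node with k classified candidates gives 1/k per
candidate; candidates lacking a term at the level vote for the reserved
"unclassified" term).  The family's consensus class is the term with the
largest summed vote mass and its score is that mass divided by the number
of member nodes — counting unannotated members, so a six-node family with
2.25 units of vote mass on its majority term scores 2.25/6 = 0.375.  A
singleton with one classified candidate therefore scores exactly 1.

The score measures consistency of the structural matches within a family,
not confidence that any of them is the true structure.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import (
    ONTOLOGY_LEVELS,
    UNCLASSIFIED,
    CandidateStructure,
    ChemTaxonomy,
    FamilyClassification,
    MolecularNetwork,
    NetworkValidationError,
    NodeVote,
    sorted_family_ids,
)

logger = logging.getLogger(__name__)


def node_votes(cluster_id: int,
               taxonomies: Sequence[Optional[ChemTaxonomy]],
               level: str,
               weights: Optional[Sequence[Fraction]] = None) -> NodeVote:
    """Fractional class votes of one node at one ontology level.

    ``taxonomies`` holds one record per classifiable candidate (``None``
    marks a candidate whose structure resolved to no taxonomy at all; such
    candidates vote "unclassified", like candidates whose record runs out
    above the requested level).  With no candidates the vote map is empty
    and the node counts as unannotated.  ``weights`` (optional, one per
    candidate) are normalized so the node's total vote mass stays 1; the
    default weights candidates equally (1/k each).
    """
    if level not in ONTOLOGY_LEVELS:
        raise ValueError(f"unknown ontology level {level!r}")
    k = len(taxonomies)
    if k == 0:
        return NodeVote(cluster_id=cluster_id, level=level, votes={})
    if weights is None:
        shares = [Fraction(1, k)] * k
    else:
        if len(weights) != k:
            raise ValueError("one weight per candidate required")
        total = sum(Fraction(w) for w in weights)
        if total <= 0:
            raise ValueError("candidate weights must sum to a positive value")
        shares = [Fraction(w) / total for w in weights]
    votes: dict[str, Fraction] = defaultdict(Fraction)
    for tax, share in zip(taxonomies, shares):
        term = tax.term_at(level) if tax is not None else None
        votes[term if term is not None else UNCLASSIFIED] += share
    return NodeVote(cluster_id=cluster_id, level=level,
                    votes={t: votes[t] for t in sorted(votes)})


def family_classification(family_id, member_votes: Sequence[NodeVote],
                          level: str) -> FamilyClassification:
    """Consensus class and score for one family at one level.

    Every member node needs a vote (possibly empty); the denominator is the
    full family size.  The reserved "unclassified" term can only win when no
    real term has positive mass.  Ties between real terms break by number of
    distinct supporting nodes, then lexicographically.
    """
    if not member_votes:
        raise NetworkValidationError(f"family {family_id!r} has no members")
    totals: dict[str, Fraction] = defaultdict(Fraction)
    supporters: dict[str, set[int]] = defaultdict(set)
    n_annotated = 0
    for v in member_votes:
        if v.level != level:
            raise ValueError(f"vote for level {v.level!r}, expected {level!r}")
        if v.annotated:
            n_annotated += 1
        for term, frac in v.votes.items():
            totals[term] += Fraction(frac)
            supporters[term].add(v.cluster_id)

    n_nodes = len(member_votes)
    real = {t: m for t, m in totals.items() if t != UNCLASSIFIED and m > 0}
    if real:
        # largest mass, then most distinct supporting nodes, then A->Z
        top = min(real, key=lambda t: (-real[t], -len(supporters[t]), t))
        score = real[top] / n_nodes
    elif totals.get(UNCLASSIFIED, Fraction(0)) > 0:
        top, score = UNCLASSIFIED, totals[UNCLASSIFIED] / n_nodes
    else:
        top, score = UNCLASSIFIED, Fraction(0)
    return FamilyClassification(
        family_id=family_id, level=level, top_class=top, score=float(score),
        vote_totals={t: float(m) for t, m in sorted(totals.items())},
        n_nodes=n_nodes, n_annotated=n_annotated,
    )


def _votes_for_network(network: MolecularNetwork,
                       candidates_by_node: Mapping[int, list[CandidateStructure]],
                       taxonomies: Mapping[tuple, Optional[ChemTaxonomy]],
                       level: str,
                       rank_weighted: bool = False,
                       source_weights: Optional[Mapping[str, float]] = None,
                       ) -> dict[int, NodeVote]:
    votes = {}
    for cid in network.nodes:
        cands = candidates_by_node.get(cid, [])
        # candidates whose structure resolved to no taxonomy record at all
        # (cache misses, key failures) cannot vote; a node left with none is
        # unannotated and contributes only to the family denominator
        voting = [c for c in cands if taxonomies.get(c.identity) is not None]
        tax_list = [taxonomies[c.identity] for c in voting]
        weights = None
        if rank_weighted or source_weights:
            weights = []
            for c in voting:
                w = Fraction(1, c.rank) if rank_weighted else Fraction(1)
                if source_weights:
                    w *= Fraction(source_weights.get(c.source, 1)).limit_denominator(10**6)
                weights.append(w)
        votes[cid] = node_votes(cid, tax_list, level, weights=weights)
    return votes


def classify_network(network: MolecularNetwork,
                     candidates_by_node: Mapping[int, list[CandidateStructure]],
                     taxonomies: Mapping[tuple, Optional[ChemTaxonomy]],
                     levels: Sequence[str] = ONTOLOGY_LEVELS,
                     rank_weighted: bool = False,
                     source_weights: Optional[Mapping[str, float]] = None,
                     ) -> tuple[pd.DataFrame, dict[int, dict[str, str]]]:
    """Score every family at every ontology level.

    Returns the classification table (one row per family x level, columns
    family_id, level, top_class, score, n_nodes, n_annotated) and a per-node
    attribute map {cluster_id: {level: family top class}} for export.

    By default every candidate votes equally; ``rank_weighted`` down-weights
    a candidate by 1/rank and ``source_weights`` scales votes per annotation
    source (both off/1 by default: all structures count equally).

    Candidate tables whose cluster ids are absent from the network are
    logged and skipped; completely disjoint id spaces raise, as that
    signals outputs from mismatched jobs.
    """
    known = set(network.nodes)
    cand_ids = {cid for cid in candidates_by_node if candidates_by_node[cid]}
    unknown = cand_ids - known
    if cand_ids and not (cand_ids & known):
        raise NetworkValidationError(
            "candidate tables and network share no cluster ids "
            f"({len(cand_ids)} candidate ids vs {len(known)} network nodes) — "
            "are these outputs from the same job?"
        )
    if unknown:
        logger.warning("skipping %d candidate cluster id(s) not in the network",
                       len(unknown))
    usable = {cid: cands for cid, cands in candidates_by_node.items() if cid in known}

    rows = []
    node_attrs: dict[int, dict[str, str]] = {cid: {} for cid in network.nodes}
    per_level_class: dict[str, dict] = {}
    for level in levels:
        votes = _votes_for_network(network, usable, taxonomies, level,
                                   rank_weighted=rank_weighted,
                                   source_weights=source_weights)
        for fid in sorted_family_ids(network.families):
            members = sorted(network.families[fid])
            fc = family_classification(fid, [votes[c] for c in members], level)
            rows.append({
                "family_id": fc.family_id, "level": fc.level,
                "top_class": fc.top_class, "score": fc.score,
                "n_nodes": fc.n_nodes, "n_annotated": fc.n_annotated,
            })
            for cid in members:
                node_attrs[cid][level] = fc.top_class
                node_attrs[cid][f"{level}_score"] = fc.score
    table = pd.DataFrame(rows, columns=["family_id", "level", "top_class",
                                        "score", "n_nodes", "n_annotated"])
    return table, node_attrs
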