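"""Independent brute-force reference implementations.

These deliberately naive routines (flood fill, plain-loop vote counting,
pairwise set intersection, count-and-sort) compute the ground truth recorded
in fixture manifests and serve as references in tests.  They must stay
independent of the library modules they check: nothing here imports from
io_network, consensus, motif_mapping or graph_export.
"""

from __future__ import annotations

from typing import Optional, Sequence


def flood_fill_families(node_ids: Sequence[int],
                        edges: Sequence[tuple[int, int]]) -> list[frozenset[int]]:
    """Connected components by explicit flood fill."""
    adjacency: dict[int, set[int]] = {n: set() for n in node_ids}
    for a, b in edges:
        if a != b:
            adjacency[a].add(b)
            adjacency[b].add(a)
    seen: set[int] = set()
    components = []
    for start in node_ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(adjacency[n] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


def count_node_votes(terms: Sequence[Optional[str]]) -> dict[str, float]:
    """Equal-weight fractional votes of one node's candidate terms.

    ``None`` stands for a candidate with no term at the level; it votes for
    the reserved term "unclassified".
    """
    if not terms:
        return {}
    votes: dict[str, float] = {}
    for t in terms:
        key = t if t is not None else "unclassified"
        votes[key] = votes.get(key, 0.0) + 1.0 / len(terms)
    return votes


def score_family(per_node_terms: Sequence[Sequence[Optional[str]]],
                 ) -> tuple[str, float]:
    """Top class and score for one family by exhaustive enumeration.

    ``per_node_terms`` holds one term list per member node (empty list =
    unannotated node).  Ties break by distinct supporting nodes, then
    alphabetically; "unclassified" wins only when nothing real has mass.
    """
    totals: dict[str, float] = {}
    supporters: dict[str, set[int]] = {}
    for idx, terms in enumerate(per_node_terms):
        for term, mass in count_node_votes(terms).items():
            totals[term] = totals.get(term, 0.0) + mass
            supporters.setdefault(term, set()).add(idx)
    n_nodes = len(per_node_terms)
    real = sorted(t for t in totals if t != "unclassified" and totals[t] > 0)
    best, best_key = None, None
    for t in real:
        # round so float-arithmetic ties are treated as exact ties
        key = (-round(totals[t], 9), -len(supporters[t]), t)
        if best_key is None or key < best_key:
            best, best_key = t, key
    if best is not None:
        return best, totals[best] / n_nodes
    if totals.get("unclassified", 0.0) > 0:
        return "unclassified", totals["unclassified"] / n_nodes
    return "unclassified", 0.0


def shared_motif_pairs(node_motifs: dict[int, set[str]],
                       pairs: Optional[Sequence[tuple[int, int]]] = None,
                       max_motif_frequency: Optional[int] = None,
                       ) -> set[tuple[int, int, str]]:
    """All (a, b, motif) triples with a < b sharing the motif.

    With ``pairs`` given, only those node pairs are considered (cosine
    scope); otherwise every pair is checked, skipping motifs carried by more
    than ``max_motif_frequency`` nodes.
    """
    out: set[tuple[int, int, str]] = set()
    if pairs is not None:
        for a, b in pairs:
            lo, hi = min(a, b), max(a, b)
            for m in node_motifs.get(lo, set()) & node_motifs.get(hi, set()):
                out.add((lo, hi, m))
        return out
    freq: dict[str, int] = {}
    for motifs in node_motifs.values():
        for m in motifs:
            freq[m] = freq.get(m, 0) + 1
    ids = sorted(node_motifs)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            for m in node_motifs[a] & node_motifs[b]:
                if max_motif_frequency is not None and freq[m] > max_motif_frequency:
                    continue
                out.add((a, b, m))
    return out


def rank_family_motifs(member_motifs: dict[int, set[str]],
                       x: int) -> list[tuple[str, int]]:
    """Count-and-sort ranking of motifs within one family."""
    counts: dict[str, int] = {}
    for motifs in member_motifs.values():
        for m in motifs:
            counts[m] = counts.get(m, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:x]
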