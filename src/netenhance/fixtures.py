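"""Seeded generator for complete, internally consistent toy input bundles.

A bundle emulates every input the workflow consumes — network node/edge
tables, a motif-assignment table, candidate-structure tables from several
sources, and a taxonomy cache over a synthetic toy ontology — together with
a YAML manifest of ground-truth outputs computed by the independent
brute-force routines in ``_bruteforce``.  Everything is derived from one
seed, so regeneration is byte-identical and tests need no downloads.

The taxonomy here is synthetic: its class level reuses four real chemical
class names so examples read naturally, but the records do not come from
any classification service.
"""

from __future__ import annotations

import random
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import _bruteforce as bf
from .chem_classify import structure_key
from .model import ONTOLOGY_LEVELS

#: class-level terms of the toy ontology
CLASS_TERMS = (
    "cinnamaldehydes",
    "coumarins and derivatives",
    "flavonoids",
    "macrolactames",
)

_SUPERCLASS = {
    "cinnamaldehydes": "phenylpropanoids and polyketides",
    "coumarins and derivatives": "phenylpropanoids and polyketides",
    "flavonoids": "phenylpropanoids and polyketides",
    "macrolactames": "organic nitrogen compounds",
}

DEFAULT_THRESHOLDS = {"p_min": 0.1, "o_min": 0.3}


def _smiles_pool(n: int) -> list[str]:
    """n distinct, trivially valid SMILES (alcohols, acids, amines)."""
    pool = []
    i = 1
    while len(pool) < n:
        c = "C" * i
        for s in (c + "O", c + "(=O)O", c + "N"):
            pool.append(s)
            if len(pool) == n:
                break
        i += 1
    return pool


def _toy_ontology(rng: random.Random, n_structures: int,
                  n_terms_per_level: int) -> tuple[list[str], dict, dict]:
    """Structures, structure -> key, structure -> level-term path."""
    smiles = _smiles_pool(n_structures)
    keys = {s: structure_key(s) for s in smiles}
    paths: dict[str, dict[str, Optional[str]]] = {}
    terms = list(CLASS_TERMS[:max(1, min(n_terms_per_level, len(CLASS_TERMS)))])
    for s in smiles:
        cls = rng.choice(terms)
        sub = f"{cls} subclass {rng.randrange(1, n_terms_per_level + 1)}"
        # a minority of records stop above the deepest levels
        depth = rng.choices((5, 4, 3), weights=(70, 20, 10))[0]
        path = {
            "kingdom": "organic compounds",
            "superclass": _SUPERCLASS[cls],
            "class": cls,
            "subclass": sub if depth >= 4 else None,
            "direct_parent": f"{sub} parent" if depth >= 5 else None,
        }
        paths[s] = path
    return smiles, keys, paths


def _percent(n: int, total: int, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100 * n) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def generate_bundle(out_dir, seed: int = 7, n_families: int = 4,
                    family_size_range: tuple[int, int] = (2, 8),
                    n_singletons: int = 4, n_motifs: int = 8,
                    n_terms_per_level: int = 4,
                    annotation_density: float = 0.7,
                    multiclass_fraction: float = 0.3,
                    n_uncached_structures: int = 4) -> dict:
    """Write a toy input bundle and its ground-truth manifest.

    Families are random connected graphs; candidates are drawn from the toy
    ontology with per-node class mixtures controlled by
    ``multiclass_fraction``; motif probabilities and overlaps straddle the
    default filter thresholds so filtering is exercised on both sides.
    Returns the manifest (also written as ``manifest.yaml``).
    """
    lo, hi = family_size_range
    if lo > hi or lo < 2:
        raise ValueError(f"family_size_range must satisfy 2 <= lo <= hi, got {family_size_range}")
    if not 0.0 <= annotation_density <= 1.0:
        raise ValueError(f"annotation_density must lie in [0, 1], got {annotation_density}")
    if n_families < 1 or n_motifs < 1 or n_terms_per_level < 1:
        raise ValueError("n_families, n_motifs and n_terms_per_level must be positive")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    # --- network topology ---------------------------------------------
    next_id = 1
    families: list[list[int]] = []
    edges: list[tuple[int, int, float]] = []
    for _ in range(n_families):
        size = rng.randint(lo, hi)
        members = list(range(next_id, next_id + size))
        next_id += size
        families.append(members)
        shuffled = members[:]
        rng.shuffle(shuffled)
        for i in range(1, size):  # random spanning tree
            a = shuffled[i]
            b = shuffled[rng.randrange(i)]
            edges.append((min(a, b), max(a, b), round(rng.uniform(0.6, 0.99), 3)))
        for _ in range(rng.randrange(size)):  # extra in-family edges
            a, b = rng.sample(members, 2)
            edges.append((min(a, b), max(a, b), round(rng.uniform(0.6, 0.99), 3)))
    singleton_ids = list(range(next_id, next_id + n_singletons))
    next_id += n_singletons
    node_ids = [c for fam in families for c in fam] + singleton_ids

    # --- structures and candidates -------------------------------------
    smiles, keys, paths = _toy_ontology(rng, 24, n_terms_per_level)
    # a few structures stay out of the cache: classification misses
    uncached = set(rng.sample(smiles, n_uncached_structures))
    by_class: dict[str, list[str]] = {}
    for s in smiles:
        by_class.setdefault(paths[s]["class"], []).append(s)
    classes = sorted(by_class)

    lib_rows, fusion_rows, consensus_rows, pept_rows = [], [], [], []
    node_candidates: dict[int, list[str]] = {}
    for cid in node_ids:
        if rng.random() >= annotation_density:
            continue
        home = rng.choice(classes)
        k = rng.randint(1, 4)
        cands = []
        for _ in range(k):
            if rng.random() < multiclass_fraction:
                cands.append(rng.choice(smiles))
            else:
                cands.append(rng.choice(by_class[home]))
        node_candidates[cid] = cands
        route = rng.random()
        if route < 0.35:
            lib_rows.append({"cluster_id": cid, "smiles": cands[0], "inchi": "",
                             "score": round(rng.uniform(0.5, 1.0), 3)})
            for s in cands[1:]:
                fusion_rows.append((cid, s))
        elif route < 0.75:
            for s in cands:
                fusion_rows.append((cid, s))
        elif route < 0.9:
            for s in cands:
                consensus_rows.append((cid, s))
        else:
            for s in cands:
                pept_rows.append({"cluster_id": cid, "smiles": s,
                                  "score": round(rng.uniform(5, 25), 2),
                                  "fdr": round(rng.uniform(0.0, 5.0), 2)})

    def _ranked_frame(rows: list[tuple[int, str]]) -> pd.DataFrame:
        per_node: dict[int, list[str]] = {}
        for cid, s in rows:
            per_node.setdefault(cid, []).append(s)
        return pd.DataFrame(
            [{"cluster_id": cid, "smiles_list": ",".join(per_node[cid])}
             for cid in sorted(per_node)],
            columns=["cluster_id", "smiles_list"],
        )

    # --- motif assignments ---------------------------------------------
    motif_ids = [f"motif_{i}" for i in range(1, n_motifs + 1)]
    motif_rows = []
    for cid in node_ids:
        for m in rng.sample(motif_ids, rng.randrange(0, min(4, n_motifs) + 1)):
            # straddle the default thresholds on both sides
            prob = round(rng.uniform(0.0, 0.5), 3)
            overlap = round(rng.uniform(0.0, 1.0), 3)
            motif_rows.append({"cluster_id": cid, "motif_id": m,
                               "probability": prob, "overlap": overlap,
                               "annotation": ""})
    motif_rows.sort(key=lambda r: (r["cluster_id"], r["motif_id"]))

    # --- write the bundle ----------------------------------------------
    nodes_df = pd.DataFrame(
        [{"cluster_id": cid,
          "precursor_mz": round(rng.uniform(100, 1500), 4),
          "parent_mass": "",
          "family_id": ""} for cid in node_ids],
        columns=["cluster_id", "precursor_mz", "parent_mass", "family_id"],
    )
    edges_df = pd.DataFrame(
        [{"id_a": a, "id_b": b, "cosine": c} for a, b, c in sorted(edges)],
        columns=["id_a", "id_b", "cosine"],
    )
    cache_rows = [
        {"structure_key": keys[s], **{
            {"class_": "class"}.get(lv, lv): paths[s][lv] or ""
            for lv in ("kingdom", "superclass", "class", "subclass", "direct_parent")}}
        for s in smiles if s not in uncached
    ]
    cache_df = pd.DataFrame(
        cache_rows, columns=["structure_key", "kingdom", "superclass", "class",
                             "subclass", "direct_parent"]
    ).drop_duplicates(subset="structure_key").sort_values("structure_key")

    files = {
        "nodes": out / "nodes.tsv",
        "edges": out / "edges.tsv",
        "motifs": out / "motifs.tsv",
        "library": out / "library.tsv",
        "insilico_fusion": out / "insilico_fusion.tsv",
        "insilico_consensus": out / "insilico_consensus.tsv",
        "peptidic": out / "peptidic.tsv",
        "taxonomy_cache": out / "taxonomy_cache.tsv",
    }
    nodes_df.to_csv(files["nodes"], sep="\t", index=False)
    edges_df.to_csv(files["edges"], sep="\t", index=False)
    pd.DataFrame(motif_rows, columns=["cluster_id", "motif_id", "probability",
                                      "overlap", "annotation"]
                 ).to_csv(files["motifs"], sep="\t", index=False)
    pd.DataFrame(lib_rows, columns=["cluster_id", "smiles", "inchi", "score"]
                 ).to_csv(files["library"], sep="\t", index=False)
    _ranked_frame(fusion_rows).to_csv(files["insilico_fusion"], sep="\t", index=False)
    _ranked_frame(consensus_rows).to_csv(files["insilico_consensus"], sep="\t", index=False)
    pd.DataFrame(pept_rows, columns=["cluster_id", "smiles", "score", "fdr"]
                 ).to_csv(files["peptidic"], sep="\t", index=False)
    cache_df.to_csv(files["taxonomy_cache"], sep="\t", index=False)

    # --- ground truth via brute force -----------------------------------
    components = bf.flood_fill_families(node_ids, [(a, b) for a, b, _ in edges])
    multi = sorted((c for c in components if len(c) > 1), key=min)
    partition = {str(i): sorted(c) for i, c in enumerate(multi, start=1)}
    for c in components:
        if len(c) == 1:
            (cid,) = c
            partition[f"S{cid}"] = [cid]

    cached_paths = {s: paths[s] for s in smiles if s not in uncached}
    classifications: dict[str, dict[str, dict]] = {}
    for fid, members in partition.items():
        classifications[fid] = {}
        for level in ONTOLOGY_LEVELS:
            per_node_terms = []
            for cid in members:
                terms = [cached_paths[s][level]
                         for s in node_candidates.get(cid, [])
                         if s in cached_paths]
                per_node_terms.append(terms)
            top, score = bf.score_family(per_node_terms)
            classifications[fid][level] = {"top_class": top,
                                           "score": round(score, 10)}

    filtered = [r for r in motif_rows
                if r["probability"] >= DEFAULT_THRESHOLDS["p_min"]
                and r["overlap"] >= DEFAULT_THRESHOLDS["o_min"]]
    node_motifs: dict[int, set[str]] = {}
    for r in filtered:
        node_motifs.setdefault(r["cluster_id"], set()).add(r["motif_id"])
    motif_freqs = {}
    for m in motif_ids:
        n = sum(1 for motifs in node_motifs.values() if m in motifs)
        if n:
            motif_freqs[m] = {"n_nodes": n, "percent": _percent(n, len(node_ids))}
    cosine_pairs = sorted({(min(a, b), max(a, b)) for a, b, _ in edges})
    share_edges = bf.shared_motif_pairs(node_motifs, pairs=cosine_pairs)
    top_motifs = {
        fid: [list(t) for t in bf.rank_family_motifs(
            {cid: node_motifs.get(cid, set()) for cid in members}, 3)]
        for fid, members in partition.items()
    }

    n_keyed_candidates = sum(len(c) for c in node_candidates.values())
    n_classified = sum(1 for cands in node_candidates.values()
                       for s in cands if s in cached_paths)

    manifest = {
        "seed": seed,
        "parameters": {
            "n_families": n_families, "family_size_range": [lo, hi],
            "n_singletons": n_singletons, "n_motifs": n_motifs,
            "n_terms_per_level": n_terms_per_level,
            "annotation_density": annotation_density,
            "multiclass_fraction": multiclass_fraction,
            "n_uncached_structures": n_uncached_structures,
            "thresholds": dict(DEFAULT_THRESHOLDS),
        },
        "counts": {
            "nodes": len(node_ids),
            "edges": len(edges),
            "motif_rows": len(motif_rows),
            "filtered_motif_assignments": len(filtered),
            "library_hits": len(lib_rows),
            "insilico_fusion_candidates": len(fusion_rows),
            "insilico_consensus_candidates": len(consensus_rows),
            "peptidic_rows": len(pept_rows),
            "cache_entries": int(len(cache_df)),
            "motif_share_edges_cosine": len(share_edges),
            "candidates_total": n_keyed_candidates,
        },
        "classified_fraction": (round(n_classified / n_keyed_candidates, 10)
                                if n_keyed_candidates else 0.0),
        "structure_keys": {s: keys[s] for s in smiles},
        "family_partition": partition,
        "classifications": classifications,
        "motif_frequencies": motif_freqs,
        "top_motifs_x3": top_motifs,
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# hand-written six-node demo family
# ---------------------------------------------------------------------------

#: synthetic demo structures (toy ontology; class terms echo real ones)
_DEMO_STRUCTURES = {
    "CCO": "flavonoids",
    "CCCO": "flavonoids",
    "CCCCO": "flavonoids",
    "CCCCCO": "flavonoids",
    "CC(=O)O": "coumarins and derivatives",
    "CCC(=O)O": "coumarins and derivatives",
    "C=CC=O": "cinnamaldehydes",
    "CCN": "macrolactames",
}

#: per-node candidate structures of the worked six-node family: fractional
#: class votes are 1.0 + 0.25 + 1.0 (+ 0 from the coumarin-only node) = 2.25
#: units for "flavonoids" over 6 nodes -> consensus score 0.375
_DEMO_CANDIDATES = {
    1: ["CCO", "CCCO", "CCCCO", "CCCCCO"],
    2: ["CCO", "CC(=O)O", "C=CC=O", "CCN"],
    3: ["CCO", "CCCO"],
    4: ["CC(=O)O", "CCC(=O)O"],
    # nodes 5 and 6 carry no structural matches
}


def write_six_node_demo(out_dir) -> dict:
    """Write the worked six-node family as a loadable bundle.

    One family of six chained nodes, four of them annotated, whose
    class-level vote mass totals 2.25 units for "flavonoids" — the consensus
    score is therefore 2.25/6 = 0.375.  Also includes an isolated node 7
    with a single library match, the singleton convention example (score 1).
    Returns {file role: path}.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    node_ids = [1, 2, 3, 4, 5, 6, 7]
    pd.DataFrame(
        [{"cluster_id": c, "precursor_mz": 100.0 + 10 * c, "parent_mass": "",
          "family_id": ""} for c in node_ids],
        columns=["cluster_id", "precursor_mz", "parent_mass", "family_id"],
    ).to_csv(out / "nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id_a": a, "id_b": a + 1, "cosine": 0.8} for a in range(1, 6)],
        columns=["id_a", "id_b", "cosine"],
    ).to_csv(out / "edges.tsv", sep="\t", index=False)

    lib_rows = [{"cluster_id": cid, "smiles": s, "inchi": "", "score": 0.9}
                for cid, cands in sorted(_DEMO_CANDIDATES.items())
                for s in cands]
    lib_rows.append({"cluster_id": 7, "smiles": "CCO", "inchi": "", "score": 0.95})
    pd.DataFrame(lib_rows, columns=["cluster_id", "smiles", "inchi", "score"]
                 ).to_csv(out / "library.tsv", sep="\t", index=False)

    cache_rows = []
    for s, cls in sorted(_DEMO_STRUCTURES.items()):
        cache_rows.append({
            "structure_key": structure_key(s),
            "kingdom": "organic compounds",
            "superclass": _SUPERCLASS[cls],
            "class": cls,
            "subclass": f"{cls} subclass 1",
            "direct_parent": f"{cls} subclass 1 parent",
        })
    pd.DataFrame(cache_rows, columns=["structure_key", "kingdom", "superclass",
                                      "class", "subclass", "direct_parent"]
                 ).drop_duplicates(subset="structure_key"
                 ).sort_values("structure_key"
                 ).to_csv(out / "taxonomy_cache.tsv", sep="\t", index=False)

    return {"nodes": out / "nodes.tsv", "edges": out / "edges.tsv",
            "library": out / "library.tsv",
            "taxonomy_cache": out / "taxonomy_cache.tsv"}
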