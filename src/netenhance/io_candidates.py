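"""Readers for candidate-structure tables from the annotation tools.

Five source flavours are supported: spectral-library matches, two ranked
in silico exports (fusion- and consensus-scored candidate lists), and two
peptidic annotators (exact and variable matching, which report scores and
false-discovery rates).  All sources are pooled with equal standing; an
optional deduplication step collapses identical structures per node using
the precedence library > peptidic > in silico.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional, Sequence

import pandas as pd

from .dialects import Dialect, SIMPLE_INSILICO, SIMPLE_LIBRARY, SIMPLE_PEPTIDIC
from .model import SOURCES, CandidateStructure, NetworkFormatError

logger = logging.getLogger(__name__)

DEFAULT_MAX_RANK = 10
#: Documented preset for the peptidic annotators' FDR cutoff.
PEPTIDIC_FDR_PRESET = 2.5


def _clean(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s if s and s.upper() not in ("N/A", "NA", "NONE") else None


def read_library_hits(path, dialect: Dialect = SIMPLE_LIBRARY) -> list[CandidateStructure]:
    """Read spectral-library matches (one hit per node, rank 1).

    Rows without any structure string are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    col_id = dialect.column("cluster_id")
    if col_id not in df.columns:
        raise NetworkFormatError(f"{path}: missing id column {col_id!r}")
    smiles_col = dialect.column("smiles") if dialect.has("smiles") else None
    inchi_col = dialect.column("inchi") if dialect.has("inchi") else None
    score_col = dialect.column("score") if dialect.has("score") else None
    if not any(c in df.columns for c in (smiles_col, inchi_col) if c):
        raise NetworkFormatError(f"{path}: no structure column present")

    out: list[CandidateStructure] = []
    n_dropped = 0
    ranks: dict[int, int] = defaultdict(int)
    for _, row in df.iterrows():
        smiles = _clean(row[smiles_col]) if smiles_col in df.columns else None
        inchi = _clean(row[inchi_col]) if inchi_col and inchi_col in df.columns else None
        if not (smiles or inchi):
            n_dropped += 1
            continue
        score = None
        if score_col and score_col in df.columns:
            s = _clean(row[score_col])
            score = float(s) if s is not None else None
        cid = int(row[col_id])
        # usually one hit per node; extra hits get successive ranks so the
        # (cluster_id, source, rank) identity stays unique
        ranks[cid] += 1
        out.append(
            CandidateStructure(cluster_id=cid, source="library",
                               rank=ranks[cid], smiles=smiles, inchi=inchi,
                               score=score)
        )
    if n_dropped:
        logger.info("%s: dropped %d structureless hit(s)", path, n_dropped)
    return out


def read_insilico_candidates(path, dialect: Dialect = SIMPLE_INSILICO,
                             max_rank: int = DEFAULT_MAX_RANK,
                             source: str = "insilico_fusion") -> list[CandidateStructure]:
    """Read ranked in silico candidate lists.

    The export holds one row per node with a delimited, rank-ordered list of
    SMILES; lists are truncated to ``max_rank`` with source order preserved.
    """
    if source not in ("insilico_fusion", "insilico_consensus"):
        raise ValueError(f"in silico source must be a fusion/consensus flavour, got {source!r}")
    if max_rank < 1:
        raise ValueError(f"max_rank must be >= 1, got {max_rank}")
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    col_id = dialect.column("cluster_id")
    col_list = dialect.column("smiles_list")
    for c in (col_id, col_list):
        if c not in df.columns:
            raise NetworkFormatError(f"{path}: missing column {c!r}")

    out: list[CandidateStructure] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        cell = row[col_list]
        if pd.isna(cell):
            continue
        try:
            items = [s for s in (p.strip() for p in str(cell).split(dialect.list_delimiter)) if s]
        except Exception as exc:  # pragma: no cover - split rarely fails
            raise NetworkFormatError(f"{path}, line {pos + 2}: unparseable list cell") from exc
        cid = int(row[col_id])
        for rank, smiles in enumerate(items[:max_rank], start=1):
            out.append(CandidateStructure(cluster_id=cid, source=source,
                                          rank=rank, smiles=smiles))
    return out


def read_peptidic_annotations(path, dialect: Dialect = SIMPLE_PEPTIDIC,
                              source: str = "peptidic_exact",
                              fdr_cutoff: Optional[float] = None) -> list[CandidateStructure]:
    """Read peptidic annotator output (scores + FDR per match).

    No FDR cutoff is applied by default (annotations are metadata); pass
    ``fdr_cutoff=PEPTIDIC_FDR_PRESET`` for the documented 2.5 preset.  The
    cutoff is inclusive.
    """
    if source not in ("peptidic_exact", "peptidic_variable"):
        raise ValueError(f"peptidic source flavour expected, got {source!r}")
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    col_id = dialect.column("cluster_id")
    col_smiles = dialect.column("smiles")
    for c in (col_id, col_smiles):
        if c not in df.columns:
            raise NetworkFormatError(f"{path}: missing column {c!r}")
    col_fdr = dialect.column("fdr") if dialect.has("fdr") else None
    if fdr_cutoff is not None and (col_fdr is None or col_fdr not in df.columns):
        raise NetworkFormatError(
            f"{path}: FDR cutoff requested but no FDR column is mapped/present"
        )
    col_score = dialect.column("score") if dialect.has("score") else None

    out: list[CandidateStructure] = []
    ranks: dict[int, int] = defaultdict(int)
    n_cut = 0
    for _, row in df.iterrows():
        smiles = _clean(row[col_smiles])
        if smiles is None:
            continue
        fdr = None
        if col_fdr and col_fdr in df.columns:
            s = _clean(row[col_fdr])
            fdr = float(s) if s is not None else None
        if fdr_cutoff is not None and (fdr is None or fdr > fdr_cutoff):
            n_cut += 1
            continue
        score = None
        if col_score and col_score in df.columns:
            s = _clean(row[col_score])
            score = float(s) if s is not None else None
        cid = int(row[col_id])
        ranks[cid] += 1
        out.append(CandidateStructure(cluster_id=cid, source=source,
                                      rank=ranks[cid], smiles=smiles,
                                      score=score, fdr=fdr))
    if n_cut:
        logger.info("%s: FDR cutoff %.3g removed %d row(s)", path, fdr_cutoff, n_cut)
    return out


def unify_candidates(sources: Sequence[list[CandidateStructure]],
                     dedupe: bool = False) -> dict[int, list[CandidateStructure]]:
    """Pool candidates across sources into a per-node map.

    With ``dedupe`` on, candidates on the same node whose ``structure_key``
    matches collapse to one, keeping the source of highest precedence
    (library > peptidic > in silico, then lowest rank).  Keys must have been
    assigned (see ``chem_classify.assign_structure_keys``) for deduplication
    to collapse anything; keyless candidates never collapse.
    """
    pooled: dict[int, list[CandidateStructure]] = defaultdict(list)
    for source_list in sources:
        for cand in source_list:
            pooled[cand.cluster_id].append(cand)

    precedence = {s: i for i, s in enumerate(SOURCES)}

    def order(c: CandidateStructure):
        return (precedence[c.source], c.rank)

    out: dict[int, list[CandidateStructure]] = {}
    for cid in sorted(pooled):
        cands = sorted(pooled[cid], key=order)
        if dedupe:
            seen: set[str] = set()
            kept = []
            for c in cands:
                if c.structure_key is not None and c.structure_key in seen:
                    continue
                if c.structure_key is not None:
                    seen.add(c.structure_key)
                kept.append(c)
            cands = kept
        out[cid] = cands
    return out
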