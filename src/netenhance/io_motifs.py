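"""Reader and threshold filter for substructure-motif assignment tables.

A motif table links spectra ("documents", identified by the network cluster
id) to discovered substructure motifs, with two quality scores per link: the
topic-model probability and the overlap score (how much of the motif's
fragment/loss features the spectrum actually contains).  Downstream mapping
only uses links passing both thresholds; the shipped defaults are
probability >= 0.1 and overlap >= 0.3.
"""

from __future__ import annotations

import logging

import pandas as pd

from .dialects import Dialect, SIMPLE_MOTIFS
from .model import MotifAssignment, NetworkFormatError, NetworkValidationError

logger = logging.getLogger(__name__)

DEFAULT_P_MIN = 0.1
DEFAULT_O_MIN = 0.3


def read_motif_table(path, dialect: Dialect = SIMPLE_MOTIFS) -> list[MotifAssignment]:
    """Read document-motif links; duplicate (cluster, motif) rows collapse to
    the one with maximum overlap (count logged)."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    needed = ("cluster_id", "motif_id", "probability", "overlap")
    missing = [dialect.column(f) for f in needed if dialect.column(f) not in df.columns]
    if missing:
        raise NetworkFormatError(
            f"{path}: missing required column(s) {missing} (dialect {dialect.name!r})"
        )
    col = {f: dialect.column(f) for f in needed}
    ann_col = dialect.column("annotation") if dialect.has("annotation") else None

    best: dict[tuple[int, str], MotifAssignment] = {}
    n_dupes = 0
    for pos, (_, row) in enumerate(df.iterrows()):
        i = pos + 2
        try:
            cid = int(row[col["cluster_id"]])
            prob = float(row[col["probability"]])
            overlap = float(row[col["overlap"]])
        except (TypeError, ValueError) as exc:
            raise NetworkFormatError(f"{path}, line {i}: unparseable value") from exc
        motif = str(row[col["motif_id"]])
        annotation = None
        if ann_col and ann_col in df.columns and pd.notna(row[ann_col]):
            annotation = str(row[ann_col])
        try:
            a = MotifAssignment(cluster_id=cid, motif_id=motif,
                                probability=prob, overlap=overlap,
                                annotation=annotation)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"{path}, line {i}: {exc}") from exc
        key = (cid, motif)
        if key in best:
            n_dupes += 1
            if a.overlap > best[key].overlap:
                best[key] = a
        else:
            best[key] = a
    if n_dupes:
        logger.info("%s: collapsed %d duplicate (cluster, motif) row(s)", path, n_dupes)
    return sorted(best.values(), key=lambda a: (a.cluster_id, a.motif_id))


def filter_assignments(assignments: list[MotifAssignment],
                       p_min: float = DEFAULT_P_MIN,
                       o_min: float = DEFAULT_O_MIN,
                       strict: bool = False) -> list[MotifAssignment]:
    """Keep assignments passing both thresholds.

    Comparisons are inclusive (``>=``) by default; ``strict=True`` switches
    to strict ``>`` for users reproducing pipelines that filtered that way.
    Output is ordered by (cluster id, motif id).
    """
    for name, v in (("p_min", p_min), ("o_min", o_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if strict:
        kept = [a for a in assignments if a.probability > p_min and a.overlap > o_min]
    else:
        kept = [a for a in assignments if a.probability >= p_min and a.overlap >= o_min]
    return sorted(kept, key=lambda a: (a.cluster_id, a.motif_id))
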