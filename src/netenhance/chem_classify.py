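"""Chemical-taxonomy lookup for candidate structures.

Candidate structures are mapped to a five-level chemical ontology
(kingdom, superclass, class, subclass, direct parent) through a pluggable
provider.  The default provider is a local tab-separated cache keyed by a
structure key — the first block of the structure's InChIKey, so that
stereoisomeric spellings of the same scaffold share a key.  An online
classification service can stand behind the same interface, but the offline
cache is the test and default path: cache misses are reported as
unclassified, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol

from rdkit import Chem, RDLogger
from rdkit.Chem.inchi import MolFromInchi

from .model import (
    CandidateStructure,
    ChemTaxonomy,
    NetworkFormatError,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")


class StructureKeyError(ValueError):
    """The structure string could not be parsed into a molecule."""


def structure_key(smiles: Optional[str] = None, inchi: Optional[str] = None,
                  full_key: bool = False) -> str:
    """Stable structure identifier with InChIKey semantics.

    The default returns the first (connectivity) block of the InChIKey, so
    stereoisomers match; ``full_key=True`` keeps the complete key.  SMILES is
    preferred when both strings are given.
    """
    if smiles:
        mol = Chem.MolFromSmiles(smiles)
        label = smiles
    elif inchi:
        mol = MolFromInchi(inchi)
        label = inchi
    else:
        raise StructureKeyError("no structure string given")
    if mol is None:
        raise StructureKeyError(f"unparseable structure {label!r}")
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise StructureKeyError(f"no InChIKey for structure {label!r}")
    return key if full_key else key.split("-")[0]


def assign_structure_keys(candidates: list[CandidateStructure],
                          full_key: bool = False) -> tuple[list[CandidateStructure], int]:
    """Return candidates with ``structure_key`` filled in.

    Unparseable structures are excluded (they cannot vote); the second
    return value is the number excluded, which is also logged.
    """
    import dataclasses

    keyed: list[CandidateStructure] = []
    n_failed = 0
    for c in candidates:
        try:
            key = structure_key(c.smiles, c.inchi, full_key=full_key)
        except StructureKeyError:
            n_failed += 1
            continue
        keyed.append(dataclasses.replace(c, structure_key=key))
    if n_failed:
        logger.info("excluded %d candidate(s) with unparseable structures", n_failed)
    return keyed, n_failed


class TaxonomyProvider(Protocol):
    def lookup(self, key: str) -> Optional[ChemTaxonomy]: ...


@dataclass
class TaxonomyCache:
    """Offline structure-key -> taxonomy map (pure lookups)."""

    entries: dict[str, ChemTaxonomy] = field(default_factory=dict)
    provenance: str = ""

    def lookup(self, key: str) -> Optional[ChemTaxonomy]:
        return self.entries.get(key)

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "TaxonomyCache":
        """Load a cache table with columns
        structure_key, kingdom, superclass, class, subclass, direct_parent."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        # the class_ model field is written as "class" in the file
        colnames = ["structure_key", "kingdom", "superclass", "class",
                    "subclass", "direct_parent"]
        missing = [c for c in colnames if c not in df.columns]
        if missing:
            raise NetworkFormatError(f"{path}: cache missing column(s) {missing}")
        entries: dict[str, ChemTaxonomy] = {}
        for _, row in df.iterrows():
            key = str(row["structure_key"])
            if key in entries:
                raise NetworkFormatError(f"{path}: duplicate structure key {key!r}")

            def term(col: str) -> Optional[str]:
                v = row[col]
                return None if pd.isna(v) or str(v) == "" else str(v)

            entries[key] = ChemTaxonomy(
                kingdom=term("kingdom"), superclass=term("superclass"),
                class_=term("class"), subclass=term("subclass"),
                direct_parent=term("direct_parent"),
            )
        return cls(entries=entries, provenance=provenance or str(path))

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {"structure_key": k, "kingdom": t.kingdom, "superclass": t.superclass,
             "class": t.class_, "subclass": t.subclass,
             "direct_parent": t.direct_parent}
            for k, t in sorted(self.entries.items())
        ]
        pd.DataFrame(rows, columns=["structure_key", "kingdom", "superclass",
                                    "class", "subclass", "direct_parent"]
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class ClassificationResult:
    """Taxonomies per candidate plus bookkeeping counts."""

    taxonomies: dict[tuple[int, str, int], Optional[ChemTaxonomy]]
    n_candidates: int
    n_classified: int

    @property
    def classified_fraction(self) -> float:
        return self.n_classified / self.n_candidates if self.n_candidates else 0.0


def classify_candidates(candidates_by_node: Mapping[int, list[CandidateStructure]],
                        provider: TaxonomyProvider) -> ClassificationResult:
    """Resolve every keyed candidate to a taxonomy record or an explicit
    unclassified marker (``None``)."""
    taxonomies: dict[tuple[int, str, int], Optional[ChemTaxonomy]] = {}
    n_total = 0
    n_hit = 0
    for cid in sorted(candidates_by_node):
        for cand in candidates_by_node[cid]:
            if cand.structure_key is None:
                continue  # keyless candidates were excluded upstream
            n_total += 1
            tax = provider.lookup(cand.structure_key)
            if tax is not None:
                n_hit += 1
            taxonomies[cand.identity] = tax
    return ClassificationResult(taxonomies=taxonomies, n_candidates=n_total,
                                n_classified=n_hit)
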