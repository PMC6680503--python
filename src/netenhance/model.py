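"""Core domain model for enhanced molecular networks.

A molecular network groups fragmented mass features (nodes, identified by a
cluster id) into molecular families — connected components of the spectral
cosine-similarity graph.  On top of that base network the package layers
substructure motifs discovered by topic modelling of fragmentation spectra
and candidate chemical structures from library matching and in silico
annotation, and summarises each family by its consensus chemical class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

#: Family id carried by nodes with no cosine edge (export convention).
SINGLETON = -1

#: The five levels of the chemical ontology, shallow to deep.
ONTOLOGY_LEVELS = ("kingdom", "superclass", "class", "subclass", "direct_parent")

#: Reserved vote term for candidates lacking a term at the requested level.
UNCLASSIFIED = "unclassified"

#: Candidate-structure sources, in deduplication precedence order.
SOURCES = (
    "library",
    "peptidic_exact",
    "peptidic_variable",
    "insilico_fusion",
    "insilico_consensus",
)

FamilyId = Union[int, str]


class NetworkFormatError(ValueError):
    """An input table or graphml file violates the expected format."""


class NetworkValidationError(ValueError):
    """Parsed inputs are internally inconsistent (ids, ranges, partitions)."""


@dataclass
class NodeRecord:
    """One fragmented mass feature (network node)."""

    cluster_id: int
    precursor_mz: Optional[float] = None
    parent_mass: Optional[float] = None
    family_id: int = SINGLETON
    extra_attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cluster_id = int(self.cluster_id)
        if self.precursor_mz is not None and not self.precursor_mz > 0:
            raise NetworkValidationError(
                f"node {self.cluster_id}: precursor m/z must be positive, "
                f"got {self.precursor_mz}"
            )


@dataclass(frozen=True)
class CosineEdge:
    """Spectral-similarity edge between two mass features."""

    id_a: int
    id_b: int
    cosine: Optional[float] = None
    edge_kind: str = "cosine"

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise NetworkValidationError(f"self-loop on cluster {self.id_a}")
        if self.cosine is not None and not 0.0 <= self.cosine <= 1.0:
            raise NetworkValidationError(
                f"cosine {self.cosine} outside [0, 1] on edge "
                f"{self.id_a}-{self.id_b}"
            )

    @property
    def pair(self) -> tuple[int, int]:
        """Unordered endpoint pair, normalised low-high."""
        return (self.id_a, self.id_b) if self.id_a < self.id_b else (self.id_b, self.id_a)


@dataclass(frozen=True)
class MotifEdge:
    """Edge drawn between two nodes that share a substructure motif."""

    id_a: int
    id_b: int
    motif_id: str
    edge_kind: str = "motif"

    def __post_init__(self) -> None:
        if not self.id_a < self.id_b:
            raise NetworkValidationError(
                f"motif edge endpoints must be ordered: {self.id_a}, {self.id_b}"
            )


@dataclass
class MolecularNetwork:
    """Nodes, cosine edges and the family (connected-component) partition.

    ``families`` maps family id -> member cluster ids.  Multi-member families
    carry integer ids numbered from 1; each singleton node forms its own
    family keyed ``"S<cluster_id>"`` (its node record carries the
    :data:`SINGLETON` sentinel, mirroring the usual export convention).
    """

    nodes: dict[int, NodeRecord]
    edges: list[CosineEdge]
    families: dict[FamilyId, frozenset[int]]
    motif_edges: list[MotifEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for fid, members in self.families.items():
            if seen & members:
                raise NetworkValidationError(
                    f"family {fid!r} overlaps another family"
                )
            seen |= members
        if seen != set(self.nodes):
            raise NetworkValidationError(
                "families do not partition the node set: "
                f"{len(seen)} covered vs {len(self.nodes)} nodes"
            )
        for e in self.edges:
            if e.id_a not in self.nodes or e.id_b not in self.nodes:
                raise NetworkValidationError(
                    f"edge {e.id_a}-{e.id_b} references unknown node"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def family_of(self, cluster_id: int) -> FamilyId:
        for fid, members in self.families.items():
            if cluster_id in members:
                return fid
        raise KeyError(cluster_id)

    def cosine_pairs(self) -> dict[tuple[int, int], float]:
        """Unordered connected pairs -> best cosine (duplicates collapse to max)."""
        pairs: dict[tuple[int, int], float] = {}
        for e in self.edges:
            c = e.cosine if e.cosine is not None else float("nan")
            prev = pairs.get(e.pair)
            # max over duplicates; a real value beats NaN (missing cosine)
            if prev is None or prev != prev or (c == c and c > prev):
                pairs[e.pair] = c
        return pairs


@dataclass(frozen=True)
class MotifAssignment:
    """Link between a spectrum (document / cluster id) and a motif.

    ``probability`` is the topic-model association; ``overlap`` measures how
    much of the motif's fragment/loss features occur in the spectrum.
    """

    cluster_id: int
    motif_id: str
    probability: float
    overlap: float
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("probability", "overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NetworkValidationError(
                    f"{name} {v} outside [0, 1] for cluster {self.cluster_id}, "
                    f"motif {self.motif_id}"
                )


@dataclass(frozen=True)
class CandidateStructure:
    """One putative structure for one node from one annotation source."""

    cluster_id: int
    source: str
    rank: int
    smiles: Optional[str] = None
    inchi: Optional[str] = None
    score: Optional[float] = None
    fdr: Optional[float] = None
    structure_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise NetworkValidationError(f"unknown candidate source {self.source!r}")
        if self.rank < 1:
            raise NetworkValidationError(f"rank must be >= 1, got {self.rank}")
        if not (self.smiles or self.inchi):
            raise NetworkValidationError(
                f"candidate for cluster {self.cluster_id} has neither SMILES nor InChI"
            )

    @property
    def identity(self) -> tuple[int, str, int]:
        return (self.cluster_id, self.source, self.rank)


@dataclass(frozen=True)
class ChemTaxonomy:
    """Five-level chemical ontology record: a rooted path, shallow to deep.

    An absent level implies every deeper level is absent too.
    """

    kingdom: Optional[str] = None
    superclass: Optional[str] = None
    class_: Optional[str] = None
    subclass: Optional[str] = None
    direct_parent: Optional[str] = None

    def __post_init__(self) -> None:
        levels = self.as_tuple()
        deeper_present = False
        for term in reversed(levels):
            if term is not None:
                deeper_present = True
            elif deeper_present:
                raise NetworkValidationError(
                    f"ontology record is not a rooted path: {levels}"
                )

    def as_tuple(self) -> tuple[Optional[str], ...]:
        return (self.kingdom, self.superclass, self.class_, self.subclass, self.direct_parent)

    def term_at(self, level: str) -> Optional[str]:
        if level not in ONTOLOGY_LEVELS:
            raise ValueError(f"unknown ontology level {level!r}")
        return self.as_tuple()[ONTOLOGY_LEVELS.index(level)]


@dataclass
class NodeVote:
    """Fractional class votes of one node at one ontology level."""

    cluster_id: int
    level: str
    votes: dict[str, float]

    @property
    def annotated(self) -> bool:
        return bool(self.votes)


@dataclass
class FamilyClassification:
    """Consensus class of one family at one ontology level.

    ``score`` is the fraction of the family's nodes (counting unannotated
    members in the denominator) whose fractional candidate votes support
    ``top_class``.  A high score signals consistency among the structural
    matches, not confidence in their correctness.
    """

    family_id: FamilyId
    level: str
    top_class: str
    score: float
    vote_totals: dict[str, float]
    n_nodes: int
    n_annotated: int


@dataclass(frozen=True)
class MotifFrequency:
    """How often a motif occurs across the whole network."""

    motif_id: str
    n_nodes_with_motif: int
    percent_of_nodes: float


def sorted_family_ids(ids: Iterable[FamilyId]) -> list[FamilyId]:
    """Deterministic family ordering: numbered families first, then singletons."""
    return sorted(ids, key=lambda f: (isinstance(f, str), f if isinstance(f, str) else int(f)))
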