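"""Column-mapping dialects for the heterogeneous table exports.

Molecular-networking platforms name their columns differently between the
classical (MS-Cluster) and feature-based (MZmine2) pipelines, and every
annotation tool ships its own headers.  Rather than guessing, every reader
takes an explicit ``Dialect`` — a mapping from the logical fields the reader
needs to the column names in the file.  Presets for the common exports are
shipped here; a user can load their own from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


@dataclass(frozen=True)
class Dialect:
    """Logical field -> column name mapping for one table format."""

    name: str
    columns: dict = field(default_factory=dict)
    #: delimiter inside ranked-list cells (in silico exports), if any
    list_delimiter: str = ","
    #: field separator of the file itself
    sep: str = "\t"

    def column(self, logical: str) -> str:
        try:
            return self.columns[logical]
        except KeyError:
            raise KeyError(
                f"dialect {self.name!r} does not map logical field {logical!r}"
            ) from None

    def has(self, logical: str) -> bool:
        return logical in self.columns


# -- network tables ---------------------------------------------------------

#: Classical molecular-networking job: pairs file + clusterinfo summary.
GNPS_CLASSICAL = Dialect(
    name="gnps_classical",
    columns={
        "id_a": "CLUSTERID1",
        "id_b": "CLUSTERID2",
        "cosine": "Cosine",
        "cluster_id": "cluster index",
        "precursor_mz": "precursor mass",
        "parent_mass": "parent mass",
        "family_id": "componentindex",
    },
)

#: Feature-based molecular-networking job.
GNPS_FEATURE_BASED = Dialect(
    name="gnps_feature_based",
    columns={
        "id_a": "CLUSTERID1",
        "id_b": "CLUSTERID2",
        "cosine": "Cosine",
        "cluster_id": "cluster index",
        "precursor_mz": "precursor mass",
        "parent_mass": "parent mass",
        "family_id": "componentindex",
    },
)

#: Plain headers used by the fixture bundles and the documentation examples.
SIMPLE_NETWORK = Dialect(
    name="simple_network",
    columns={
        "id_a": "id_a",
        "id_b": "id_b",
        "cosine": "cosine",
        "cluster_id": "cluster_id",
        "precursor_mz": "precursor_mz",
        "parent_mass": "parent_mass",
        "family_id": "family_id",
    },
)

# -- motif table ------------------------------------------------------------

#: ms2lda.org export of document-motif links.
MS2LDA = Dialect(
    name="ms2lda",
    columns={
        "cluster_id": "document",
        "motif_id": "motif",
        "probability": "probability",
        "overlap": "overlap",
        "annotation": "annotation",
    },
    sep=",",
)

SIMPLE_MOTIFS = Dialect(
    name="simple_motifs",
    columns={
        "cluster_id": "cluster_id",
        "motif_id": "motif_id",
        "probability": "probability",
        "overlap": "overlap",
        "annotation": "annotation",
    },
)

# -- candidate tables -------------------------------------------------------

#: Spectral-library match export.
GNPS_LIBRARY = Dialect(
    name="gnps_library",
    columns={
        "cluster_id": "#Scan#",
        "smiles": "Smiles",
        "inchi": "INCHI",
        "score": "MQScore",
    },
)

SIMPLE_LIBRARY = Dialect(
    name="simple_library",
    columns={
        "cluster_id": "cluster_id",
        "smiles": "smiles",
        "inchi": "inchi",
        "score": "score",
    },
)

#: In silico annotation export, one row per node with a delimited ranked list
#: (fusion-scored candidates).
NAP_FUSION = Dialect(
    name="nap_fusion",
    columns={"cluster_id": "cluster index", "smiles_list": "FusionSMILES"},
)

#: Same layout, consensus-scored list.
NAP_CONSENSUS = Dialect(
    name="nap_consensus",
    columns={"cluster_id": "cluster index", "smiles_list": "ConsensusSMILES"},
)

SIMPLE_INSILICO = Dialect(
    name="simple_insilico",
    columns={"cluster_id": "cluster_id", "smiles_list": "smiles_list"},
)

#: Peptidic annotators: exact database matching.
DEREPLICATOR = Dialect(
    name="dereplicator",
    columns={
        "cluster_id": "Scan",
        "smiles": "SMILES",
        "score": "Score",
        "fdr": "FDR",
    },
)

#: Peptidic annotators: variable (one modified residue) matching.
VARQUEST = Dialect(
    name="varquest",
    columns={
        "cluster_id": "Scan",
        "smiles": "SMILES",
        "score": "Score",
        "fdr": "FDR",
    },
)

SIMPLE_PEPTIDIC = Dialect(
    name="simple_peptidic",
    columns={
        "cluster_id": "cluster_id",
        "smiles": "smiles",
        "score": "score",
        "fdr": "fdr",
    },
)

PRESETS: dict[str, Dialect] = {
    d.name: d
    for d in (
        GNPS_CLASSICAL,
        GNPS_FEATURE_BASED,
        SIMPLE_NETWORK,
        MS2LDA,
        SIMPLE_MOTIFS,
        GNPS_LIBRARY,
        SIMPLE_LIBRARY,
        NAP_FUSION,
        NAP_CONSENSUS,
        SIMPLE_INSILICO,
        DEREPLICATOR,
        VARQUEST,
        SIMPLE_PEPTIDIC,
    )
}


def get_dialect(name: str) -> Dialect:
    """Look up a shipped preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown dialect {name!r}; available: {sorted(PRESETS)}"
        ) from None


def load_dialect(path) -> Dialect:
    """Load a user-supplied dialect from a YAML file.

    Expected keys: ``name``, ``columns`` (mapping), optional
    ``list_delimiter`` and ``sep``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "columns" not in raw:
        raise ValueError(f"dialect file {path} must define a 'columns' mapping")
    return Dialect(
        name=str(raw.get("name", "custom")),
        columns=dict(raw["columns"]),
        list_delimiter=str(raw.get("list_delimiter", ",")),
        sep=str(raw.get("sep", "\t")),
    )
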