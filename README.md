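# netenhance

Integrates the outputs of mass-spectrometry metabolome-mining tools into one
enhanced molecular network. Untargeted LC–MS/MS experiments yield thousands
of fragmentation spectra; molecular networking groups them into *molecular
families* (connected components of a spectral cosine-similarity graph),
topic modelling of the spectra discovers substructure motifs (Mass2Motifs),
and library matching plus in silico annotation propose candidate structures
per spectrum. Each tool ships its own file format, which makes their
combined interpretation tedious. `netenhance` reads all of them, matches
features by cluster id, and writes a single annotated network (graphml, for
Cytoscape) plus tab-separated summaries.

It is aimed at metabolomics and natural-products researchers who already ran
the upstream tools (a molecular-networking platform, a substructure
discovery service, spectral-library search, in silico annotators) and want
family-level chemical-class overviews and substructure maps without custom
scripts.

## The consensus chemical-classification score

Every candidate structure is mapped to a five-level chemical ontology
(kingdom → superclass → class → subclass → direct parent) through a local
taxonomy cache keyed by the connectivity block of the structure's InChIKey.
At each level, every annotated node splits one unit of vote mass equally
over its candidates' class terms: a node with *k* classified candidates
contributes 1/*k* per candidate. For a family *F* with |*F*| member nodes
(annotated or not), the consensus class at a level is

    top_class = argmax_c  Σ_{i ∈ F} v_i(c),      score = max_c Σ_{i ∈ F} v_i(c) / |F|

where v_i(c) is node *i*'s fractional vote for class term *c*. A six-node
family whose votes total 2.25 units for its majority term therefore scores
2.25/6 = 0.375; a singleton node with a single classified match scores
exactly 1. The score measures *consistency* of the structural matches
within a family — not confidence that any match is the true structure.

Substructure motifs pass a probability ≥ 0.1 and overlap ≥ 0.3 filter
(configurable), then appear as per-node attributes (pie-chart slices sized
by overlap), as extra edges between nodes sharing a motif, as per-family
"top x most shared motifs" lists, and as a network-wide frequency table
(counts and half-up-rounded percentages of nodes).

## Worked example

The package ships a seeded generator that writes a complete toy input
bundle (network tables, motif table, candidate tables from three sources,
taxonomy cache over a synthetic ontology):

```sh
netenhance fixtures --out-dir bundle --seed 7
# bundle written to bundle (23 nodes, 21 edges)

netenhance all \
  --nodes bundle/nodes.tsv --edges bundle/edges.tsv \
  --motifs bundle/motifs.tsv --library bundle/library.tsv \
  --insilico-fusion bundle/insilico_fusion.tsv \
  --peptidic-exact bundle/peptidic.tsv \
  --taxonomy-cache bundle/taxonomy_cache.tsv --out-prefix run
```

This writes `run.graphml` (the enhanced network), three summary tables and
a run manifest recording every threshold used. Class-level rows of
`run_family_classes.tsv`:

```
family_id  level  top_class                  score  n_nodes  n_annotated
1          class  cinnamaldehydes            0.50   4        4
2          class  cinnamaldehydes            0.25   2        1
3          class  coumarins and derivatives  0.25   8        5
4          class  macrolactames              0.40   5        3
S20        class  coumarins and derivatives  1.00   1        1
S21        class  unclassified               0.00   1        0
```

Family 1 has four nodes, all annotated, and half of its total vote mass
falls on "cinnamaldehydes" — a moderately consistent family. `S20` is a
singleton with one classified match (score 1 by construction), and `S21`
is a singleton with no classifiable candidate. `run_motif_frequencies.tsv`
lists, per motif, how many nodes carry it after filtering and the
percentage of all network nodes that is:

```
motif_id  n_nodes_with_motif  percent_of_nodes
motif_1   3                   13.0
motif_2   5                   21.7
```

The same functionality is available as a library (`netenhance.build_network`,
`classify_network`, `motif_share_edges`, ...); the `classify` and `motifs`
subcommands run the two halves of the workflow independently.

## Output files

| file | contents |
|---|---|
| `<prefix>.graphml` | nodes with family/class/motif attributes; cosine and motif multi-edges (`edge_kind`), stable ids `c<N>`/`m<N>` |
| `<prefix>_family_classes.tsv` | family_id, level, top_class, score, n_nodes, n_annotated |
| `<prefix>_motif_frequencies.tsv` | motif_id, n_nodes_with_motif, percent_of_nodes |
| `<prefix>_top_motifs.tsv` | family_id, rank, motif_id, n_member_nodes |
| `<prefix>_run_manifest.yaml` | full configuration, versions, drop/skip counts |

See `docs/methods.md` for the scoring conventions, tie-breaking rules and
the design decisions behind them.
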