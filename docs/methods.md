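# Methods

## Scope and data model

`netenhance` post-processes the outputs of upstream mass-spectrometry
tools; it performs no spectral processing itself. Its inputs are:

1. a molecular network — nodes are fragmented mass features identified by a
   positive integer cluster id, edges carry a modified-cosine spectral
   similarity (thresholded upstream, typically at 0.6–0.7; stored here, not
   enforced);
2. a motif table linking spectra ("documents") to substructure motifs with
   a topic-model probability and an overlap score, each in [0, 1];
3. candidate-structure tables from up to five sources: spectral-library
   hits, two ranked in silico exports, and two peptidic annotators
   (exact and variable matching) that also report FDRs;
4. a taxonomy cache mapping structure keys to five-level chemical-ontology
   records (kingdom, superclass, class, subclass, direct parent — a rooted
   path: an absent level implies all deeper levels absent).

Molecular families are connected components of the cosine graph. By
default they are recomputed from connectivity, with deterministic
numbering (components ordered by smallest member id, numbered from 1);
alternatively the export's family column is trusted after being validated
against connectivity. Nodes without edges carry the conventional sentinel
family id −1 in exports, but are scored as one-member families, keyed
`S<cluster_id>` in the classification table — the worked singleton
convention (one classified match → score 1) requires treating each
singleton individually rather than pooling everything labelled −1.

Duplicate edges over the same unordered pair are kept as a multiset and
flagged; consumers use the maximum cosine.

## Structure keys and taxonomy lookup

Candidates are keyed by the first (connectivity) block of their InChIKey,
computed with RDKit from SMILES (preferred) or InChI. Ranked in silico
lists frequently enumerate stereoisomers of one scaffold; connectivity-block
matching makes them share a cache entry. Full-key matching is available via
a flag. Candidates whose structure string fails to parse are excluded from
voting with a logged count.

The default taxonomy provider is an offline TSV cache; lookups are pure and
misses are reported as explicit unclassified markers, never guessed. A
candidate with no taxonomy record at all (key failure or cache miss) cannot
vote; a node left with zero classifiable candidates is unannotated and
contributes only to its family's denominator. A candidate whose record
exists but runs out of terms above the requested level votes for the
reserved term "unclassified" — so deeper ontology levels naturally score
lower as annotations thin out, but "unclassified" can only be reported as a
family's top class when no real term has positive mass.

## The consensus score

At each ontology level, an annotated node with k classifiable candidates
gives 1/k vote mass to each candidate's term. Family vote totals are the
per-term sums over member nodes; the consensus class is the term with the
largest total and the score divides that total by the number of member
nodes **including unannotated ones** (the worked six-node example has two
unannotated nodes and a denominator of 6: 2.25/6 = 0.375). Consequences,
all covered by tests: scores lie in [0, 1]; the score is 1 exactly when
every member is annotated and votes unanimously; total vote mass across
terms (including "unclassified") equals the number of annotated nodes.

Vote mass is accumulated with exact rational arithmetic
(`fractions.Fraction`) and converted to float only at the reporting
boundary, so conservation holds exactly and tie detection is not at the
mercy of floating-point summation order.

Ties for the top class break by (a) larger number of distinct supporting
nodes, then (b) alphabetical term order — documented because the underlying
convention is otherwise unspecified. All sources vote with equal weight and
all five levels are computed independently (no enforcement that a family's
subclass be a child of its class); per-source weights and rank-weighted
voting exist as configuration but default off, mirroring the pooled
"all structures count equally" convention. Deduplication of identical
structures per node (by structure key, precedence library > peptidic >
in silico) is likewise off by default: each structural match counts.

## Motif mapping

Assignments are filtered by probability ≥ 0.1 and overlap ≥ 0.3 by default.
Comparisons are inclusive; a strict-mode flag switches to `>` for users
matching pipelines that filtered strictly. Raising either threshold never
retains more assignments, and filtering is idempotent (property-tested).

Attached to nodes, motifs are ordered by overlap descending; pie-chart
slices use the raw overlap values, with a remainder slice when they sum
below 1 and proportional rescaling when they sum above 1 (the overlap
definition does not bound the per-node sum; rescaling keeps slices
interpretable).

Motif-share edges default to `cosine_pairs` scope — one motif edge per
cosine-connected pair and shared motif, alongside the original cosine edge,
matching how enhanced networks are usually drawn. An `all_pairs` scope
connects any two nodes sharing a motif (useful for spotting relatives not
linked by cosine similarity) and is gated by a maximum motif frequency
(default 50 nodes) to avoid quadratic blow-up for ubiquitous motifs.

"Most shared" motifs per family are ranked by the number of member nodes
carrying the motif (ties by motif id); a summed-overlap ranking is
available behind a flag. The frequency table counts distinct nodes per
motif and reports percentages of all network nodes, rounded half-up at the
requested precision — half-up because the documented example frequencies
(7.7%, 3.7%, 0.45%, 24%, 1.8%, 3.0%) are all reproduced exactly under that
rule.

## Serialization

The enhanced graphml is built as a canonically ordered multigraph — nodes
sorted by cluster id, cosine edges before motif edges, ids `c<N>`/`m<N>`
assigned in sorted order, attribute keys declared once — and serialized
with networkx. Identical inputs produce byte-identical files, and a
write → read → write cycle reproduces the file exactly (tested). Node-level
class attributes copy the family's consensus so network viewers can colour
by class; motif lists serialize as a delimited string plus one numeric
overlap attribute per motif. Summary tables are UTF-8 TSV with fixed
headers.

Column-name differences between upstream exports are handled by explicit
dialects (logical field → column name); presets ship for the common
classical/feature-based network exports, the motif-table export and the
five candidate sources, and custom dialects load from YAML. Nothing is
guessed from headers.

## Synthetic data

The fixture generator emulates the structure of all four inputs from one
seed: families as random connected graphs (default 4 families of 2–8
nodes plus 4 singletons), candidates drawn from a toy five-level ontology
whose class terms echo four real chemical classes, per-node class mixtures
controlled by a multiclass fraction (default 0.3), annotation density 0.7,
a few structures deliberately missing from the cache (default 4) and motif
probabilities/overlaps drawn to straddle the filter thresholds on both
sides. Ground truth in the bundle manifest is computed by independent
brute-force routines (flood fill, plain-loop vote counting, pairwise motif
intersection, count-and-sort) that import nothing from the modules they
check. Regeneration under one seed is byte-identical.

What the toy bundle does **not** emulate: real fragmentation spectra,
realistic cosine distributions, chemically meaningful structures (the
structure pool is simple alcohols/acids/amines chosen to parse cleanly),
or a real chemical ontology. Passing tests therefore demonstrate the
integration and scoring arithmetic, not annotation quality on real data —
on real data the score inherits all upstream limitations (database
coverage, in silico ranking errors), which is exactly why it is framed as
a consistency measure.

A separate hand-written bundle encodes the documented six-node worked
family: per-node class-level vote fractions 1.0, 0.25, 1.0 and 0 (plus two
unannotated nodes) put 2.25 units on "flavonoids", reproducing the
documented score 0.375, together with a singleton carrying one library match
(score 1). The documented example fixes only the vote totals, not the
per-node candidate multiplicities; this bundle realises them with the
smallest convenient candidate sets.

## Numerical and degenerate-input conventions

- Probability/overlap/cosine values are validated into [0, 1]; violations
  are row-level errors naming the line.
- Self-loop edges are dropped (logged); duplicate (cluster, motif) rows
  collapse to the maximum overlap (logged).
- An empty family is an error; an empty network yields header-only tables.
- Candidate tables whose ids are entirely disjoint from the network are a
  hard error (mismatched upstream jobs); partial mismatches are logged and
  skipped.
- In silico ranked lists truncate at max_rank (default 10, recorded in the
  run manifest); the peptidic FDR cutoff defaults to off, with 2.5 shipped
  as a documented preset, applied inclusively.

## Problem sizes

Tests and the acceptance script run on toy instances: bundles of ~20–30
nodes, randomized oracle-equivalence sweeps of 1000 small instances
(≤ 15 nodes, ≤ 8 candidates, ≤ 6 class terms), and a 6228-node edge-free
network for the percentage arithmetic. These sizes exercise every code
path; the algorithms are linear to quadratic in nodes and edges and handle
full-scale networks (thousands of nodes) without special handling.

## Known limitations

- The online taxonomy client interface is defined (`TaxonomyProvider`) but
  only the offline cache ships; populating a cache for new structures is
  the user's responsibility.
- Trust-column family validation renumbers inconsistent components rather
  than attempting repair.
- The score treats all candidate sources as equally reliable; per-source
  weights exist but no guidance is provided for choosing them.
- No statistical enrichment testing of class terms within families — the
  consensus score is a majority measure only.
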