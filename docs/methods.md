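# Methods

This note documents the models and procedures implemented in orthopan, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Genome model and ingest

A genome is an ordered list of contigs plus a flat list of gene features.
Coordinates are 0-based half-open internally; the GenBank boundary is
1-based inclusive, so internal `start = GenBank start − 1`. Strand is ±1.
Compound (`join(...)`) locations are concatenated exon-wise in feature order
and flagged; partial features at contig ends are taken at their recorded
coordinates.

A CDS with a `/translation` qualifier keeps it verbatim — annotations from
reference genomes are valuable as-is and are never re-derived. A CDS without
one is translated from its nucleotide span with the record's
`/transl_table` (default: bacterial table 11), trailing stop stripped; an
internal stop in a non-pseudo CDS triggers a warning, not an error. Features
carrying `/pseudo` become pseudogenes and never carry a protein.

Identifier sanitation makes genome ids, contig accessions and locus tags
unique across the whole data set (locally assembled genomes frequently
collide). A colliding identifier becomes `<original>_dupN` with N the
smallest positive integer that collides with neither already-assigned names
nor any original identifier elsewhere in the input — this makes the repair
deterministic for a fixed input order and idempotent.

GC% uses only unambiguous A/C/G/T (N excluded from the denominator, and
lowercase accepted); coding density counts each base once under overlapping
CDS.

## Orthology

Real data sets should use a dedicated orthology tool; its tab-separated
assignment table (first column orthogroup id, one column per genome, cells
comma-separated locus tags) is ingested directly, and genes missing from the
table become singleton groups (recorded by a policy flag).

For self-contained runs a classical reciprocal-best-hit (RBH) inference is
built in: Smith–Waterman local alignments (BLOSUM62, gap open 11, extend 1 —
the community-default protein scoring) between all inter-genome protein
pairs; per query and target genome the best hit by score passing
`min_identity` (default 30%, computed over aligned residue columns) and
`min_coverage` (default 0.5 of the shorter sequence); reciprocal pairs form
edges; orthogroups are connected components (single linkage). Score ties
break lexicographically by locus tag, and group ids are assigned from the
sorted member lists, so the output is deterministic and independent of
genome input order.

Known limitation, by construction: under gene loss, a gene whose true
ortholog is absent from another genome can form a spurious reciprocal pair
with an unrelated protein that clears the thresholds, merging two families.
The RBH path is a desk-scale stand-in; it recovers planted partitions
exactly when families are present in all genomes or divergence is low and
paralogy absent (the regime the tests pin), and it is not a substitute for
graph/MCL-based tools on real data.

Percent identity between two proteins is computed from a global
Needleman–Wunsch alignment under the same scoring, as
100 · (identical columns) / (columns with a residue on both sides) — gap
columns, terminal or internal, are excluded from the denominator. The pair
is canonically ordered before aligning so the value is exactly symmetric.
The alternative convention (identity over full alignment length) gives
systematically lower values; the choice is recorded here because published
figures rarely state theirs.

## Pan-genome statistics

Presence means copy number ≥ 1 throughout; no higher threshold is applied.
Accumulation curves average pan(k) = |orthogroups in ≥ 1 of the first k
genomes| and core(k) = |orthogroups in all of the first k| over either
`n_orders` seeded random genome orderings (default 100, seed 42, both
recorded in the output) or every permutation (`all_orders=True`, feasible to
G ≈ 8). The occupancy spectrum counts orthogroups by the exact number of
genomes containing them. Venn partitions (2–6 genomes, the rendering limit
of typical Venn libraries; counts are computed regardless) assign each
orthogroup present in the subset to the exact set of subset genomes
containing it — a true partition of the union. Differential queries demand
presence in *every* include genome and absence from *every* exclude genome;
a genome named in both sets yields an empty result rather than an error. A
fractional-presence extension point (`min_fraction`) was considered and left
out: the all-genomes semantics is the documented behaviour.

## KEGG module completeness

The module definition language is parsed by a recursive-descent parser with
operator binding, from tightest: `+`/`-` (complex subunits; a `-` marks the
following member optional, and a chain `K1-K2-K3` marks all trailing members
optional), `,` (alternatives), space (sequential steps). `--` is a gap
placeholder for a reaction with no assigned KO; parentheses group; `M#####`
atoms reference other modules. Parse errors (unbalanced parentheses,
dangling operators, illegal tokens) carry the 0-based failure position.
Serialisation re-inserts parentheses only where needed, and
`parse(serialize(tree))` reproduces the tree exactly (property-tested on
random corpora).

Completeness of a definition given a genome's KO set is the recursive value
v: atom → 1 if present else 0; gap → 1 (option: 0, for analyses that treat
unknown reactions as missing); complex → 1 iff every non-optional subunit is
1; alternation → max over branches; step sequence → arithmetic mean of its
steps. The mean-of-steps rule is what makes completeness a fraction rather
than a boolean — a displayed value of 0.75 means three of four steps
satisfiable — and is the one semantic choice here that published platforms
leave unstated; it is therefore pinned by an oracle test (exhaustive
truth-table enumeration over all KO subsets) rather than by any external
reference. Nested module references are resolved recursively when the
referenced definition is supplied (cycles evaluate to 0), otherwise treated
as unsatisfied with a warning.

Annotation propagation: for each KO carried directly by ≥ 1 member of an
orthogroup, every member lacking that direct annotation gains a
`propagated` entry citing the source orthogroup. Only direct entries seed
propagation, so the operation is idempotent, and direct entries are never
modified. The completeness matrix can be computed with or without
propagated KOs; each cell records the satisfied atoms, whether any of them
was available only by propagation, and per-KO gene counts (the numbers
drawn inside heatmap squares). KO presence is per genome — any gene carrying
the KO satisfies the atom regardless of pathway position.

## Functional category profiles

Category distributions count distinct genes per (category, genome); a gene
with several categories contributes to each of them but is counted once in
the per-genome denominator, so per-category numerators may sum above 100% —
standard COG reporting, and stated in the output docs rather than silently
renormalised. Proportion mode adds an explicit `unannotated` row so that
unannotated + annotated (each gene once) accounts for every gene; the
denominator is all genes by default, with `annotated_genes` as an option
since published bar charts use either.

## Core-genome phylogeny

The relaxed single-copy core keeps orthogroups with exactly one copy in
every genome where they occur and at most `max_missing` genomes lacking
them (default 0). Multi-copy orthogroups are excluded at any `max_missing`
— paralogy confounds the species signal — so selections are nested across
`max_missing` values.

Per-orthogroup alignments are supplied by a pluggable aligner; the built-in
fallback pads sequences with trailing gaps to equal length, which is exact
for the substitution-only synthetic data and inadequate for real indel-rich
data (use an external aligner there). Concatenation records per-orthogroup
column ranges; genomes missing an orthogroup receive all-gap columns.

Distances are p-distances with pairwise deletion (per-pair comparable
columns; complete deletion discards too much on gappy super-alignments); a
pair with zero comparable columns is an error rather than a guess. The tree
is classical neighbor joining with two determinism rules: Q-criterion ties
break lexicographically on cluster labels, and a negative branch-length
estimate is clamped to zero with the deficit moved to its sister branch
(pair sum preserved, then floored at zero). For additive inputs the NJ tree
reproduces the input distances exactly (tested to 1e-9 and cross-checked
against an independent implementation); two taxa yield a single evenly
split edge. Maximum-likelihood inference and bootstrap are out of scope; the
Newick output feeds any external tool.

## Regions, Circos data

Region views take a window of `window_bp` (default 8000 — typical operon
scale) on each side of the anchor gene, clipped to the contig with no
wrap-around. In comparisons, one track per genome carrying an ortholog of
the anchor (the first by coordinate when several; an all-tracks mode is a
noted extension), flipped when the ortholog's strand differs from the
reference anchor — the flip mirrors coordinates within the window and is an
involution. Links join features of consecutive tracks sharing an
orthogroup, weighted by pairwise amino-acid identity (pseudogene links carry
0). "Homolog" in the Circos rings means member of the same orthogroup; the
per-ORF presence value is the best identity to a co-member in that genome
(absent = null), and raw identities are emitted — binning/colour scales
belong to the renderer.

## Search

Bare terms match case-insensitively as substrings of any indexed field
(search-bar ergonomics); `field:` prefixed terms match whole tokens of that
field. `*` is the only wildcard (any run of characters). Operators bind
NOT > AND > OR, adjacency is implicit AND, keywords are case-insensitive.
Results are always sorted by (genome id, locus tag). No ranking or stemming.

## Result store and archives

One SQLite file holds genomes, contigs, genes, orthogroups and memberships,
identities, typed annotations with provenance, module definitions,
completeness, Newick trees and run metadata. Every default parameter that
influences a result (seed, `n_orders`, `max_missing`, RBH thresholds,
orthology source) is written to `run_metadata`, so any derived figure is
reproducible from the store alone; absent optional analyses leave their
tables empty and are flagged there. Foreign keys are enforced; a violation
aborts the build and removes the partial file. Archives are gzip-compressed
tars holding the database plus a manifest (schema version, tool version,
SHA-256); import verifies the checksum and refuses any other schema version
outright — no migration is attempted at schema version 1.

## Synthetic data

The generator states a small panel of closely related bacterial isolates:
6 genomes, 30 ancestral protein families of 60–150 aa (uniform random
sequence starting with Met), per-genome per-residue substitution probability
0.05 drawn from BLOSUM62-positive exchanges (keeps mutated proteins
alignable, as real accepted mutations are), gene loss 0.10, duplication
0.05, pseudogenization 0.05, and a 0.20 chance that a gene lacks its direct
KO annotation (these are the propagation test cases). Those defaults are a
realistic desk-scale cartoon of a within-genus panel — ~90% mean identity
inside families, a soft core around two-thirds of families — and are fixed;
tests vary them only where a scenario calls for a different stated world
(e.g. no paralogs for RBH-recovery checks, since duplicates and protein-less
pseudogenes are invisible to a protein RBH method).

Proteins are back-translated with one fixed codon per amino acid (table 11)
plus a TAA stop, laid out on one contig per genome with fixed 100-bp
spacers, strands drawn at random, and written as valid GenBank. The truth
tables (orthogroups, KO/COG assignments, module definitions, expected
completeness) are emitted alongside; expected completeness is computed by an
evaluator that operates on the generator's own construction structures,
never through the package parser, so agreement is a genuine two-route check.
Everything is deterministic per seed.

What the generator does **not** emulate — and what a green test therefore
does not establish: insertions/deletions (the fallback aligner relies on
this), rearrangements and horizontal transfer, intergenic sequence
composition, rRNA/tRNA features, codon-usage bias, and realistic genome
sizes. Conclusions about alignment quality, synteny breakage or annotation
noise on real data need real data.

## Numerical and degeneracy choices

- Identity of an alignment with zero residue columns: 0.0 by convention.
- Empty proteome in RBH inference: contributes targets only.
- `differential_query` with include ∩ exclude ≠ ∅: empty result.
- Venn regions with zero orthogroups are reported (explicit zeros).
- NJ on 2 taxa: single edge, split evenly; < 2 taxa: error.
- Selection yielding no core orthogroups: explicit error advising a larger
  `max_missing` (never a silent empty tree).
- All randomness (accumulation orderings, generator) flows through
  numpy `default_rng` with recorded seeds.
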