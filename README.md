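# orthopan

Orthology-centric comparative genomics for small-to-medium panels of
annotated bacterial genomes, as a Python library.

Comparative studies of bacterial genomes revolve around a single object: the
**orthogroup** — the set of genes across genomes descended from one ancestral
gene. Once genes are partitioned into orthogroups, one matrix answers most
questions: the orthogroup × genome **copy-number (presence) matrix**. From
it, orthopan computes the statistics and plot-ready data that a comparative
genomics platform serves:

- **Pan/core-genome analysis** — accumulation curves (mean pan- and
  core-genome size as genomes are added in random or exhaustively enumerated
  orders), the occupancy spectrum (number of orthogroups present in exactly
  *j* genomes; singletons at *j* = 1, the core at *j* = *G*), Venn partitions
  for 2–6 genomes, and differential queries (orthogroups conserved in one set
  of genomes and absent from another).
- **KEGG metabolic-module completeness** — a parser for the KEGG module
  definition language (`+` complex subunits, `-` optional subunits, `,`
  alternatives, space-separated steps, `--` gaps, parenthesised groups,
  nested `M#####` references) and a recursive evaluator: an atom scores 1 if
  its KO is present, a complex requires all non-optional subunits, an
  alternation takes the best branch, and a step sequence averages its steps,
  so completeness is a fraction in [0, 1]. Unannotated genes can inherit KOs
  from their orthogroup co-members (**annotation propagation**), with
  provenance tracked.
- **Core-genome phylogeny** — relaxed single-copy core selection (single-copy
  wherever present, missing from at most `max_missing` genomes),
  concatenated super-alignments with partition bookkeeping, p-distances with
  pairwise gap deletion, and a deterministic neighbor-joining species tree
  (Newick out). External aligners/ML tools remain pluggable.
- **Region and Circos comparison data** — gene-neighborhood tracks around an
  anchor gene with strand normalisation and identity-weighted ortholog
  links, and per-ORF reference rings (GC%, best-homolog identity per
  comparison genome, strand, contig boundaries, homolog-count histogram) as
  JSON for any renderer.
- **Search** — a query language with wildcards, `AND`/`OR`/`NOT`, quoted
  phrases and field prefixes over locus tags, gene names, products, genome
  names and KO/COG/Pfam ids.
- **A SQLite result store** — every computed result plus full run metadata in
  one file, exportable as a checksummed `.tar.gz` archive and re-importable
  elsewhere.

Orthogroups come either from an external orthology tool's assignment table
(tab-separated, one column per genome) or, for self-contained desk-scale
runs, from a built-in reciprocal-best-hit inference (BLOSUM62 local
alignments, gap open 11 / extend 1; orthogroups are connected components of
the reciprocal-best-hit graph). A synthetic-genome generator
(`orthopan.synthetic`) plants gene families with known orthology, KO/COG
annotations and module completeness, so the whole pipeline runs and is
testable without any download.

## Worked example

```python
import tempfile
from orthopan import store as st
from orthopan.synthetic import FixtureConfig, generate_fixture

with tempfile.TemporaryDirectory() as td:
    paths, truth = generate_fixture(FixtureConfig(seed=2), f"{td}/fx")
    store = st.run_pipeline(
        f"{td}/fx", f"{td}/results.db",
        orthogroup_table=f"{td}/fx/orthogroups.tsv",
        ko_table=f"{td}/fx/ko.tsv",
        cog_table=f"{td}/fx/cog.tsv",
        modules_table=f"{td}/fx/modules.tsv",
        max_missing=1,
    )
    print(store.occupancy_spectrum().counts)
    print(store.completeness_matrix(use_propagated=True).to_frame())
    print(store.tree("species"))
```

This prints (exactly, for seed 2):

```
{1: 0, 2: 0, 3: 0, 4: 7, 5: 10, 6: 13}
              g1        g2        g3        g4        g5        g6
M90001  1.000000  1.000000  1.000000  1.000000  1.000000  1.000000
M90002  1.000000  1.000000  1.000000  1.000000  1.000000  1.000000
M90003  0.666667  0.666667  0.666667  0.666667  0.666667  0.666667
((g1:0.04173016965,(g2:0.03638354853,g6:0.04615145515):0.006105699321):0.000650486188,(g3:0.04900424341,g5:0.04143053919):0.001223491876,g4:0.04664674498);
```

The spectrum reads: 13 orthogroups are present in all six genomes (the
core), ten in five genomes, seven in four, and there are no singletons. In
the completeness matrix 1.0 means every step of the module's definition is
satisfied by the genome's KO set; 0.667 means two of three sequential steps
are. The last line is the NJ species tree in Newick, branch lengths in
substitutions per aligned site.

The `examples/` directory has one short script per capability (ingest and
genome summaries; orthology and pan-genome statistics; KEGG completeness
with propagation; the core-genome tree; the store with region/Circos/search
queries), each printing the numbers it computes and a line on what they
mean.

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic panel from the
given seed, runs the complete pipeline (ingest → orthology → pan-genome
statistics → KO propagation and module completeness → core-genome NJ tree →
store build → archive export/import round trip), prints a one-line summary
to stderr and writes its JSON result object to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
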