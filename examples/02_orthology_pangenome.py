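"""Infer orthogroups by reciprocal best hits and explore the pan-genome.

Runs the built-in RBH inference on a low-divergence panel, then prints the
occupancy spectrum (how many orthogroups occur in exactly j genomes), the
mean pan/core accumulation curves, a Venn partition of three genomes and a
differential query (present in g1 and g2, absent from g3).
"""

import tempfile

from orthopan.ingest import extract_sequences, parse_genbank
from orthopan.orthology import infer_orthogroups, presence_matrix
from orthopan.pangenome import (
    accumulation_curves,
    differential_query,
    occupancy_spectrum,
    venn_partitions,
)
from orthopan.synthetic import FixtureConfig, generate_fixture

cfg = FixtureConfig(n_genomes=4, n_families=15, divergence=0.05,
                    paralog_rate=0.0, pseudogene_rate=0.0, loss_rate=0.15, seed=4)
with tempfile.TemporaryDirectory() as td:
    paths, truth = generate_fixture(cfg, td)
    genomes = [parse_genbank(p, genome_id=g) for g, p in sorted(paths.items())]
    proteomes = {g.genome_id: extract_sequences(g, "protein") for g in genomes}

ogset = infer_orthogroups(proteomes)  # BLOSUM62 local alignments, RBH graph
matrix = presence_matrix(ogset, sorted(proteomes))
print(f"{len(ogset.groups)} orthogroups over {len(matrix.genome_ids)} genomes")

spectrum = occupancy_spectrum(matrix)
print("occupancy spectrum (genomes -> orthogroups):", spectrum.counts)
print(f"  core size {spectrum.core_size}, singletons {spectrum.n_singletons}")

curves = accumulation_curves(matrix, all_orders=True)
print("\npan/core accumulation (means over all genome orderings):")
print(curves.to_frame().round(2).to_string(index=False))

regions = venn_partitions(matrix, ["g1", "g2", "g3"])
print("\nVenn regions (signature -> orthogroups):")
for sig, n in sorted(regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
    print(f"  {'&'.join(sorted(sig)):12s} {n}")

hits = differential_query(matrix, include=["g1", "g2"], exclude=["g3"])
print(f"\nconserved in g1+g2, absent from g3: {hits or 'none'}")
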