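import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from orthopan.ingest import ContigRecord, GeneFeature, GenomeRecord
from orthopan.synthetic import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default 6-genome synthetic panel written to disk, with truth tables."""
    out = tmp_path_factory.mktemp("fixture")
    paths, truth = generate_fixture(FixtureConfig(seed=20240501), out)
    return out, paths, truth


@pytest.fixture(scope="session")
def parsed_fixture(fixture_dir):
    from orthopan.ingest import parse_genbank

    _out, paths, truth = fixture_dir
    genomes = [parse_genbank(p, genome_id=g) for g, p in sorted(paths.items())]
    return genomes, truth


def make_genome(genome_id: str, genes: list[tuple[str, int, int, int, str]],
                contig_len: int = 5000, seq: str | None = None) -> GenomeRecord:
    """Hand-built genome: genes = [(locus, start, end, strand, protein)]."""
    sequence = seq if seq is not None else ("ACGT" * (contig_len // 4 + 1))[:contig_len]
    acc = f"{genome_id}_c1"
    feats = [
        GeneFeature(
            locus_tag=tag, contig=acc, start=s, end=e, strand=st,
            feature_kind="CDS" if prot else "pseudogene",
            protein_seq=prot or None,
            nucleotide_seq=sequence[s:e],
            product=f"{tag} product",
        )
        for tag, s, e, st, prot in genes
    ]
    return GenomeRecord(
        genome_id=genome_id,
        display_name=genome_id,
        contigs=[ContigRecord(accession=acc, sequence=sequence)],
        features=feats,
    )
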