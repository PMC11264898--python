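"""GenBank parsing, identifier sanitation, sequence extraction, summaries."""

import warnings
from pathlib import Path

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from oracles import revcomp, translate11
from conftest import make_genome
from orthopan.ingest import (
    FeatureCoordinateError,
    GenBankParseError,
    extract_sequences,
    genome_summary,
    parse_genbank,
    sanitize_identifiers,
)


def _write_gbk(path: Path, seq: str, features: list[SeqFeature]) -> Path:
    rec = SeqRecord(
        Seq(seq), id="ctg1", name="ctg1",
        description="test contig",
        annotations={"molecule_type": "DNA", "organism": "Testus testus"},
    )
    rec.features = [SeqFeature(FeatureLocation(0, len(seq)), type="source")] + features
    SeqIO.write([rec], str(path), "genbank")
    return path


@pytest.fixture()
def two_cds_file(tmp_path):
    # gene1 on +, gene2 on -; neither carries a translation qualifier
    gene1 = "ATGGCTGAAAAACTGTAA"          # MAEKL
    gene2 = "ATGCCGCAGTGGTATTGA"          # MPQWY
    seq = "A" * 50 + gene1 + "C" * 30 + revcomp(gene2) + "G" * 40
    f1 = SeqFeature(
        FeatureLocation(50, 50 + len(gene1), strand=1), type="CDS",
        qualifiers={"locus_tag": ["T_0001"], "product": ["protein one"]},
    )
    s2 = 50 + len(gene1) + 30
    f2 = SeqFeature(
        FeatureLocation(s2, s2 + len(gene2), strand=-1), type="CDS",
        qualifiers={"locus_tag": ["T_0002"], "product": ["protein two"]},
    )
    return _write_gbk(tmp_path / "two.gbk", seq, [f1, f2]), gene1, gene2


def test_parse_two_cds_strands(two_cds_file):
    path, gene1, gene2 = two_cds_file
    g = parse_genbank(path, genome_id="T")
    cds = [f for f in g.features if f.feature_kind == "CDS"]
    assert len(cds) == 2
    plus, minus = cds
    assert (plus.strand, minus.strand) == (1, -1)
    # minus-strand protein equals translation of the reverse complement span
    assert minus.nucleotide_seq == gene2
    assert minus.protein_seq == translate11(gene2)
    # no translation qualifier: protein equals independent table-11 translation
    assert plus.protein_seq == translate11(gene1)


def test_translation_qualifier_kept_verbatim(tmp_path):
    gene = "ATGGCTGAAAAACTGTAA"
    seq = "T" * 10 + gene + "T" * 10
    feat = SeqFeature(
        FeatureLocation(10, 10 + len(gene), strand=1), type="CDS",
        qualifiers={"locus_tag": ["V_0001"], "translation": ["MXXXX"]},
    )
    g = parse_genbank(_write_gbk(tmp_path / "v.gbk", seq, [feat]))
    assert g.features[0].protein_seq == "MXXXX"  # no re-translation


def test_pseudo_qualifier_yields_pseudogene(tmp_path):
    gene = "ATGGCTTAATAAACTGTAA"  # internal stop, as a pseudogene would have
    seq = "T" * 10 + gene + "T" * 10
    feat = SeqFeature(
        FeatureLocation(10, 10 + len(gene), strand=1), type="CDS",
        qualifiers={"locus_tag": ["P_0001"], "pseudo": [""]},
    )
    g = parse_genbank(_write_gbk(tmp_path / "p.gbk", seq, [feat]))
    f = g.features[0]
    assert f.feature_kind == "pseudogene"
    assert f.protein_seq is None


def test_coordinates_internal_zero_based(two_cds_file):
    path, gene1, _ = two_cds_file
    g = parse_genbank(path)
    f = g.features[0]
    assert (f.start, f.end) == (50, 50 + len(gene1))
    contig = g.contig(f.contig)
    assert contig.sequence[f.start:f.end] == gene1


def test_parse_errors(tmp_path):
    empty = tmp_path / "empty.gbk"
    empty.write_text("")
    with pytest.raises(GenBankParseError, match="empty.gbk"):
        parse_genbank(empty)

    # feature beyond the contig end -> feature-level error naming the locus
    seq = "ATGC" * 10
    feat = SeqFeature(
        FeatureLocation(10, 400, strand=1), type="CDS",
        qualifiers={"locus_tag": ["BAD_0001"]},
    )
    bad = _write_gbk(tmp_path / "bad.gbk", seq, [feat])
    with pytest.raises(FeatureCoordinateError, match="BAD_0001"):
        parse_genbank(bad)


class TestSanitizeIdentifiers:
    def test_cross_genome_collision_renamed(self):
        a = make_genome("A", [("GENE_0001", 0, 30, 1, "MAA")])
        b = make_genome("B", [("GENE_0001", 0, 30, 1, "MCC")])
        fixed, renames = sanitize_identifiers([a, b])
        assert fixed[0].features[0].locus_tag == "GENE_0001"
        assert fixed[1].features[0].locus_tag == "GENE_0001_dup1"
        assert len(renames) == 1

    def test_unique_input_untouched(self):
        a = make_genome("A", [("A_0001", 0, 30, 1, "MAA")])
        b = make_genome("B", [("B_0001", 0, 30, 1, "MCC")])
        fixed, renames = sanitize_identifiers([a, b])
        assert renames == {}
        assert [f.locus_tag for g in fixed for f in g.features] == ["A_0001", "B_0001"]

    def test_triple_collision_and_idempotence(self):
        gs = [
            make_genome(f"G{i}", [("X_0001", 0, 30, 1, "MAA")]) for i in range(3)
        ]
        fixed, renames = sanitize_identifiers(gs)
        tags = [g.features[0].locus_tag for g in fixed]
        assert tags == ["X_0001", "X_0001_dup1", "X_0001_dup2"]
        assert len(renames) == 2
        again, renames2 = sanitize_identifiers(fixed)
        assert renames2 == {}
        assert [g.features[0].locus_tag for g in again] == tags

    def test_contig_accessions_deduplicated(self):
        a = make_genome("A", [("A_0001", 0, 30, 1, "MAA")])
        b = make_genome("B", [("B_0001", 0, 30, 1, "MCC")])
        b.contigs[0].accession = a.contigs[0].accession
        b.features[0].contig = a.contigs[0].accession
        fixed, renames = sanitize_identifiers([a, b])
        accs = {c.accession for g in fixed for c in g.contigs}
        assert len(accs) == 2
        # the feature follows its renamed contig
        assert fixed[1].features[0].contig == fixed[1].contigs[0].accession


class TestExtractSequences:
    def test_protein_mode_counts_and_order(self):
        g = make_genome("A", [
            ("A_0002", 100, 130, 1, "MBB"),
            ("A_0001", 0, 30, 1, "MAA"),
            ("A_0003", 200, 230, -1, "MCC"),
        ])
        recs = extract_sequences(g, "protein")
        assert [r.id for r in recs] == ["A_0001", "A_0002", "A_0003"]  # genomic order
        assert [str(r.seq) for r in recs] == ["MAA", "MBB", "MCC"]

    def test_pseudogene_excluded_from_protein_mode(self):
        g = make_genome("A", [("A_0001", 0, 30, 1, "MAA"), ("A_0002", 50, 80, 1, "")])
        assert [r.id for r in extract_sequences(g, "protein")] == ["A_0001"]
        assert [r.id for r in extract_sequences(g, "nucleotide")] == ["A_0001", "A_0002"]

    def test_fasta_round_trip(self, tmp_path):
        g = make_genome("A", [("A_0001", 0, 30, 1, "MAA"), ("A_0002", 50, 80, 1, "MCC")])
        recs = extract_sequences(g, "protein")
        path = tmp_path / "prot.faa"
        SeqIO.write(recs, str(path), "fasta")
        back = list(SeqIO.parse(str(path), "fasta"))
        assert [(r.id, str(r.seq)) for r in recs] == [(r.id, str(r.seq)) for r in back]

    def test_no_cds_warns(self):
        g = make_genome("A", [("A_0001", 0, 30, 1, "")])  # only a pseudogene
        with pytest.warns(UserWarning, match="no CDS"):
            assert extract_sequences(g, "protein") == []


class TestGenomeSummary:
    def test_gc_percent(self):
        g = make_genome("A", [], seq="ATGC")
        assert genome_summary(g).gc_percent == 50.0

    def test_n_excluded_from_gc_denominator(self):
        g = make_genome("A", [], seq="ATGCNNNN")
        assert genome_summary(g).gc_percent == 50.0

    def test_coding_density_disjoint(self):
        g = make_genome(
            "A", [("A_1", 0, 100, 1, "M" * 33), ("A_2", 500, 700, 1, "M" * 66)],
            contig_len=1000,
        )
        assert genome_summary(g).coding_density == pytest.approx(0.3)

    def test_coding_density_counts_overlap_once(self):
        g = make_genome(
            "A", [("A_1", 0, 200, 1, "M"), ("A_2", 100, 300, 1, "M")],
            contig_len=1000,
        )
        assert genome_summary(g).coding_density == pytest.approx(0.3)

    def test_fixture_bookkeeping(self, parsed_fixture):
        genomes, truth = parsed_fixture
        for g in genomes:
            s = genome_summary(g)
            t = truth.summaries[g.genome_id]
            assert s.total_length == t["total_length"]
            assert s.gc_percent == pytest.approx(t["gc_percent"])
            assert s.n_cds == t["n_cds"]

    def test_zero_length_errors(self):
        g = make_genome("A", [], seq="")
        with pytest.raises(ValueError):
            genome_summary(g)
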