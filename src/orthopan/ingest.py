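"""Parsing of annotated bacterial genomes from GenBank flat files.

The genome model is deliberately small: a genome is an ordered list of
contigs plus a flat list of gene features.  Coordinates are stored 0-based
half-open (GenBank is 1-based inclusive at the file boundary); strand is
+1/-1.  CDS features keep the ``/translation`` qualifier verbatim when it is
present and are otherwise translated from their nucleotide span with the
record's translation table (bacterial table 11 by default).  Features with a
``/pseudo`` qualifier become pseudogenes and carry no protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigRecord",
    "GeneFeature",
    "GenomeRecord",
    "GenomeSummary",
    "GenBankParseError",
    "FeatureCoordinateError",
    "parse_genbank",
    "sanitize_identifiers",
    "extract_sequences",
    "genome_summary",
]

FeatureKind = Literal["CDS", "pseudogene", "rRNA", "tRNA", "other"]


class GenBankParseError(ValueError):
    """Raised when a GenBank file cannot be parsed at all."""


class FeatureCoordinateError(ValueError):
    """Raised when a feature's coordinates fall outside its contig."""


@dataclass
class ContigRecord:
    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    locus_tag: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: int  # +1 / -1
    feature_kind: FeatureKind
    gene_name: str | None = None
    product: str | None = None
    protein_seq: str | None = None
    nucleotide_seq: str = ""
    is_compound: bool = False  # join() location: exons concatenated in order

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    genome_id: str
    display_name: str
    contigs: list[ContigRecord] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def contig(self, accession: str) -> ContigRecord:
        for c in self.contigs:
            if c.accession == accession:
                return c
        raise KeyError(f"no contig {accession!r} in genome {self.genome_id!r}")

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"no locus {locus_tag!r} in genome {self.genome_id!r}")

    def cds_features(self) -> list[GeneFeature]:
        """CDS features (protein-coding, pseudogenes excluded) in genomic order."""
        order = {c.accession: i for i, c in enumerate(self.contigs)}
        return sorted(
            (f for f in self.features if f.feature_kind == "CDS"),
            key=lambda f: (order[f.contig], f.start, f.locus_tag),
        )


@dataclass
class GenomeSummary:
    genome_id: str
    total_length: int
    gc_percent: float
    n_contigs: int
    n_cds: int
    coding_density: float


_KIND_BY_TYPE = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
_SKIP_TYPES = {"source", "gene"}


def parse_genbank(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Parse one annotated genome (possibly multi-record) from a GenBank file.

    Parameters
    ----------
    path:
        GenBank flat file; each record becomes one contig.
    genome_id:
        Identifier for the genome; defaults to the file stem.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises assorted ValueError subclasses
        raise GenBankParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenBankParseError(f"GenBank file {path} contains no sequence records")

    gid = genome_id if genome_id is not None else path.stem
    display = records[0].annotations.get("organism") or records[0].description or gid
    genome = GenomeRecord(genome_id=gid, display_name=str(display).strip() or gid)

    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise GenBankParseError(f"record {rec.id!r} in {path} has no sequence")
        genome.contigs.append(ContigRecord(accession=rec.id, sequence=seq))
        for feat in rec.features:
            if feat.type in _SKIP_TYPES:
                continue
            parsed = _parse_feature(feat, rec, path)
            if parsed is not None:
                genome.features.append(parsed)
    return genome


def _parse_feature(feat, rec: SeqRecord, path: Path) -> GeneFeature | None:
    quals = feat.qualifiers
    locus = quals.get("locus_tag", [None])[0]
    if feat.type not in _KIND_BY_TYPE and feat.type != "pseudogene" and locus is None:
        return None  # unannotated misc feature: not a gene
    if locus is None:
        locus = f"{rec.id}_{int(feat.location.start)}"

    pseudo = "pseudo" in quals or "pseudogene" in quals or feat.type == "pseudogene"
    kind: FeatureKind
    if pseudo:
        kind = "pseudogene"
    else:
        kind = _KIND_BY_TYPE.get(feat.type, "other")

    start, end = int(feat.location.start), int(feat.location.end)
    if not (0 <= start < end <= len(rec.seq)):
        raise FeatureCoordinateError(
            f"feature {locus!r} has coordinates [{start}, {end}) outside contig "
            f"{rec.id!r} (length {len(rec.seq)}) in {path}"
        )

    nuc = str(feat.extract(rec.seq))
    protein: str | None = None
    if kind == "CDS":
        if "translation" in quals:
            protein = quals["translation"][0]
        else:
            table = int(quals.get("transl_table", ["11"])[0])
            protein = str(Seq(nuc).translate(table=table)).rstrip("*")
            if "*" in protein:
                warnings.warn(
                    f"internal stop codon in CDS {locus!r} (not flagged pseudo)",
                    stacklevel=3,
                )

    return GeneFeature(
        locus_tag=locus,
        contig=rec.id,
        start=start,
        end=end,
        strand=int(feat.location.strand or 1),
        feature_kind=kind,
        gene_name=quals.get("gene", [None])[0],
        product=quals.get("product", [None])[0],
        protein_seq=protein,
        nucleotide_seq=nuc,
        is_compound=len(feat.location.parts) > 1,
    )


def sanitize_identifiers(
    genomes: Iterable[GenomeRecord],
) -> tuple[list[GenomeRecord], dict[tuple[str, str, str], str]]:
    """Enforce data-set-wide uniqueness of genome ids, contig accessions and
    locus tags.

    Locally assembled genomes frequently reuse accessions or locus tags;
    colliding identifiers are renamed ``<original>_dupN`` with N the smallest
    positive integer that avoids any further collision.  Deterministic for a
    fixed input order and idempotent.

    Returns the repaired genomes (input objects are not modified) and a rename
    map keyed by ``(genome_id, category, original)`` with category one of
    ``genome``/``contig``/``locus``; the genome_id key is the *original* id.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("need at least one genome")

    rename: dict[tuple[str, str, str], str] = {}
    # Names may not collide with anything already assigned nor with any
    # identifier still to come, otherwise the result depends on suffix luck.
    all_ids: set[str] = set()
    for g in genomes:
        all_ids.add(g.genome_id)
        all_ids.update(c.accession for c in g.contigs)
        all_ids.update(f.locus_tag for f in g.features)

    used: set[str] = set()

    def fresh(name: str) -> str:
        if name not in used:
            used.add(name)
            return name
        n = 1
        while f"{name}_dup{n}" in used or f"{name}_dup{n}" in all_ids:
            n += 1
        new = f"{name}_dup{n}"
        used.add(new)
        return new

    out: list[GenomeRecord] = []
    for g in genomes:
        gid = fresh(g.genome_id)
        if gid != g.genome_id:
            rename[(g.genome_id, "genome", g.genome_id)] = gid
        contig_map: dict[str, str] = {}
        contigs = []
        for c in g.contigs:
            acc = fresh(c.accession)
            if acc != c.accession:
                rename[(g.genome_id, "contig", c.accession)] = acc
            contig_map[c.accession] = acc
            contigs.append(ContigRecord(accession=acc, sequence=c.sequence))
        feats = []
        for f in g.features:
            tag = fresh(f.locus_tag)
            if tag != f.locus_tag:
                rename[(g.genome_id, "locus", f.locus_tag)] = tag
            feats.append(replace(f, locus_tag=tag, contig=contig_map[f.contig]))
        out.append(
            GenomeRecord(
                genome_id=gid,
                display_name=g.display_name,
                contigs=contigs,
                features=feats,
            )
        )
    return out, rename


def extract_sequences(
    genome: GenomeRecord, alphabet: Literal["protein", "nucleotide"]
) -> list[SeqRecord]:
    """Extract per-gene FASTA records, id = locus_tag, in genomic order.

    Protein mode yields one record per CDS (pseudogenes have no protein and
    are excluded); nucleotide mode yields one record per gene feature.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    order = {c.accession: i for i, c in enumerate(genome.contigs)}
    feats = sorted(genome.features, key=lambda f: (order[f.contig], f.start, f.locus_tag))
    records: list[SeqRecord] = []
    for f in feats:
        if alphabet == "protein":
            if f.feature_kind != "CDS" or f.protein_seq is None:
                continue
            seq = f.protein_seq
        else:
            seq = f.nucleotide_seq
        records.append(SeqRecord(Seq(seq), id=f.locus_tag, description=f.product or ""))
    if alphabet == "protein" and not records:
        warnings.warn(f"genome {genome.genome_id!r} has no CDS; empty proteome")
    return records


def genome_summary(genome: GenomeRecord) -> GenomeSummary:
    """Main characteristics of a genome: size, GC%, contig/CDS counts, coding
    density.

    GC% uses only unambiguous bases (N excluded from the denominator); coding
    density counts each base once even where CDS overlap.
    """
    total = sum(c.length for c in genome.contigs)
    if total == 0:
        raise ValueError(f"genome {genome.genome_id!r} has zero length")
    gc = at = 0
    for c in genome.contigs:
        s = c.sequence.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    gc_percent = 100.0 * gc / (gc + at) if (gc + at) else 0.0

    coding = 0
    cds = [f for f in genome.features if f.feature_kind == "CDS"]
    for contig in genome.contigs:
        spans = sorted(
            (f.start, f.end) for f in cds if f.contig == contig.accession
        )
        last_end = 0
        for s, e in spans:  # merge overlapping spans
            s = max(s, last_end)
            if e > s:
                coding += e - s
                last_end = e
            last_end = max(last_end, e)
    return GenomeSummary(
        genome_id=genome.genome_id,
        total_length=total,
        gc_percent=gc_percent,
        n_contigs=len(genome.contigs),
        n_cds=len(cds),
        coding_density=coding / total,
    )


def summaries_table(genomes: Iterable[GenomeRecord]):
    """Genome summaries as a pandas DataFrame (one row per genome)."""
    import pandas as pd

    rows = [vars(genome_summary(g)) for g in genomes]
    return pd.DataFrame(rows).set_index("genome_id")
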