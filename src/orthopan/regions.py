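"""Plot-ready data for genomic-region comparisons and Circos-style rings.

Region comparison lines up the neighborhood of a gene of interest with the
neighborhoods of its orthologs in other genomes; links between consecutive
tracks join genes sharing an orthogroup, weighted by amino-acid identity.
Tracks are strand-normalised: a target neighborhood whose anchor ortholog
lies on the opposite strand is mirrored (an involution) so the anchor always
points the same way.

Circos track data describes a reference genome ring by ring: per-ORF GC
content, per-comparison-genome best-homolog identity (or absence), forward/
reverse strand rings, contig boundaries, and a histogram of homolog counts
per reference protein.  Rendering is left to any Circos-style library; this
module only computes the numbers (JSON-serialisable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .ingest import GeneFeature, GenomeRecord
from .orthology import OrthogroupSet, pairwise_identity

__all__ = [
    "RegionView",
    "RegionComparison",
    "TrackSet",
    "extract_region",
    "flip_region",
    "compare_regions",
    "circos_tracks",
    "DEFAULT_WINDOW_BP",
]

DEFAULT_WINDOW_BP = 8000  # typical operon scale


@dataclass
class RegionView:
    genome_id: str
    contig: str
    window: tuple[int, int]  # bp, 0-based half-open, clipped to the contig
    features: list[GeneFeature]
    anchor: str  # locus_tag, always inside the window
    flipped: bool = False


@dataclass
class RegionComparison:
    tracks: list[RegionView]
    links: list[tuple[str, str, float]]  # (locus_a, locus_b, identity %)
    notices: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "tracks": [
                {
                    "genome_id": t.genome_id,
                    "contig": t.contig,
                    "window": list(t.window),
                    "anchor": t.anchor,
                    "flipped": t.flipped,
                    "features": [
                        {
                            "locus_tag": f.locus_tag,
                            "start": f.start,
                            "end": f.end,
                            "strand": f.strand,
                            "kind": f.feature_kind,
                            "product": f.product,
                        }
                        for f in t.features
                    ],
                }
                for t in self.tracks
            ],
            "links": [
                {"locus_a": a, "locus_b": b, "identity": i} for a, b, i in self.links
            ],
            "notices": self.notices,
        }
        return json.dumps(payload, indent=2)


def extract_region(
    genome: GenomeRecord, locus: str, window_bp: int = DEFAULT_WINDOW_BP
) -> RegionView:
    """Neighborhood of a gene: window = gene span +/- window_bp, clipped to
    the contig (no wrap-around); all overlapping features, ordered by start."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    anchor = genome.feature(locus)  # KeyError if unknown
    contig = genome.contig(anchor.contig)
    start = max(0, anchor.start - window_bp)
    end = min(contig.length, anchor.end + window_bp)
    feats = sorted(
        (
            f
            for f in genome.features
            if f.contig == anchor.contig and f.start < end and f.end > start
        ),
        key=lambda f: (f.start, f.locus_tag),
    )
    return RegionView(
        genome_id=genome.genome_id,
        contig=anchor.contig,
        window=(start, end),
        features=feats,
        anchor=locus,
    )


def flip_region(view: RegionView) -> RegionView:
    """Mirror a region within its window (strand normalisation).

    Coordinates are reflected about the window, strands negated, feature
    order re-sorted.  Applying twice restores the original view.
    """
    ws, we = view.window
    feats = [
        replace(
            f,
            start=ws + we - f.end,
            end=ws + we - f.start,
            strand=-f.strand,
        )
        for f in view.features
    ]
    feats.sort(key=lambda f: (f.start, f.locus_tag))
    return RegionView(
        genome_id=view.genome_id,
        contig=view.contig,
        window=view.window,
        features=feats,
        anchor=view.anchor,
        flipped=not view.flipped,
    )


def compare_regions(
    genomes: Mapping[str, GenomeRecord],
    anchor_genome: str,
    anchor_locus: str,
    ogset: OrthogroupSet,
    target_genomes: Sequence[str] | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> RegionComparison:
    """Compare the neighborhood of a gene with its orthologs' neighborhoods.

    One track per genome carrying an ortholog of the anchor (first by
    coordinate when several); target tracks are flipped so the ortholog's
    strand matches the reference anchor.  Links between consecutive tracks
    join every feature pair sharing an orthogroup, carrying percent
    amino-acid identity (protein-coding pairs; pseudogenes link at identity
    0).  Genomes without an ortholog are reported in ``notices``.
    """
    membership = ogset.membership()
    anchor_og = membership.get((anchor_genome, anchor_locus))
    if anchor_og is None:
        raise ValueError(
            f"anchor {anchor_locus!r} ({anchor_genome!r}) is not assigned to any orthogroup"
        )
    if target_genomes is None:
        target_genomes = [g for g in genomes if g != anchor_genome]

    ref_track = extract_region(genomes[anchor_genome], anchor_locus, window_bp)
    ref_strand = genomes[anchor_genome].feature(anchor_locus).strand
    tracks = [ref_track]
    notices: list[str] = []
    for gid in target_genomes:
        members = [
            tag for (g, tag) in ogset.groups[anchor_og] if g == gid
        ]
        if not members:
            notices.append(f"genome {gid!r} has no ortholog of {anchor_locus!r}")
            continue
        genome = genomes[gid]
        members.sort(key=lambda tag: (genome.feature(tag).contig, genome.feature(tag).start))
        tag = members[0]
        track = extract_region(genome, tag, window_bp)
        if genome.feature(tag).strand != ref_strand:
            track = flip_region(track)
        tracks.append(track)

    links: list[tuple[str, str, float]] = []
    for upper, lower in zip(tracks, tracks[1:]):
        gu, gl = genomes[upper.genome_id], genomes[lower.genome_id]
        for fu in upper.features:
            og_u = membership.get((upper.genome_id, fu.locus_tag))
            if og_u is None:
                continue
            for fl in lower.features:
                if membership.get((lower.genome_id, fl.locus_tag)) != og_u:
                    continue
                pu = gu.feature(fu.locus_tag).protein_seq
                pl = gl.feature(fl.locus_tag).protein_seq
                ident = pairwise_identity(pu, pl) if pu and pl else 0.0
                links.append((fu.locus_tag, fl.locus_tag, ident))
    return RegionComparison(tracks=tracks, links=links, notices=notices)


@dataclass
class TrackSet:
    """Circos-style ring data; every per-ORF ring indexes ``orf_order``."""

    reference: str
    orf_order: list[str]  # reference CDS locus tags in genomic order
    gc_per_orf: list[float]  # GC % of each ORF's nucleotide span
    presence: dict[str, list[float | None]]  # comparison genome -> identity or None
    forward_ring: list[bool]  # True where the ORF is on the + strand
    reverse_ring: list[bool]
    orf_positions: list[tuple[int, int]]  # cumulative (start, end) per ORF
    contig_ring: list[tuple[str, int, int]]  # (accession, cum start, cum end)
    homolog_count: list[int]  # per ORF, orthogroup members across comparisons

    def to_json(self) -> str:
        payload = {
            "reference": self.reference,
            "orf_order": self.orf_order,
            "gc_per_orf": self.gc_per_orf,
            "presence": self.presence,
            "forward_ring": self.forward_ring,
            "reverse_ring": self.reverse_ring,
            "orf_positions": [list(p) for p in self.orf_positions],
            "contig_ring": [list(c) for c in self.contig_ring],
            "homolog_count": self.homolog_count,
        }
        return json.dumps(payload, indent=2)


def _gc_percent(seq: str) -> float:
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    atgc = gc + s.count("A") + s.count("T")
    return 100.0 * gc / atgc if atgc else 0.0


def circos_tracks(
    reference: GenomeRecord,
    comparison_genomes: Sequence[GenomeRecord],
    ogset: OrthogroupSet,
) -> TrackSet:
    """Per-ORF conservation rings of a reference genome against others.

    For every reference CDS: GC% of its span; per comparison genome the best
    pairwise identity to an orthogroup co-member (None = no homolog); strand
    ring membership; and the total number of orthogroup members across the
    comparison genomes (the outer histogram).  Contig boundaries are given in
    cumulative coordinates over the ordered reference contigs.
    """
    if not comparison_genomes:
        raise ValueError("need at least one comparison genome")
    membership = ogset.membership()
    cds = reference.cds_features()
    orf_order = [f.locus_tag for f in cds]

    offsets: dict[str, int] = {}
    cum = 0
    contig_ring = []
    for c in reference.contigs:
        offsets[c.accession] = cum
        contig_ring.append((c.accession, cum, cum + c.length))
        cum += c.length

    features_by_genome = {
        g.genome_id: {f.locus_tag: f for f in g.features} for g in comparison_genomes
    }
    presence: dict[str, list[float | None]] = {
        g.genome_id: [] for g in comparison_genomes
    }
    gc_ring: list[float] = []
    fwd: list[bool] = []
    rev: list[bool] = []
    positions: list[tuple[int, int]] = []
    homolog_count: list[int] = []
    comparison_ids = {g.genome_id for g in comparison_genomes}

    for f in cds:
        gc_ring.append(_gc_percent(f.nucleotide_seq))
        fwd.append(f.strand > 0)
        rev.append(f.strand < 0)
        off = offsets[f.contig]
        positions.append((off + f.start, off + f.end))
        og = membership.get((reference.genome_id, f.locus_tag))
        members = ogset.groups.get(og, []) if og is not None else []
        homolog_count.append(
            sum(1 for (gid, _tag) in members if gid in comparison_ids)
        )
        for g in comparison_genomes:
            best: float | None = None
            for gid, tag in members:
                if gid != g.genome_id:
                    continue
                other = features_by_genome[g.genome_id].get(tag)
                if other is None or not other.protein_seq or not f.protein_seq:
                    continue
                ident = pairwise_identity(f.protein_seq, other.protein_seq)
                if best is None or ident > best:
                    best = ident
            presence[g.genome_id].append(best)

    return TrackSet(
        reference=reference.genome_id,
        orf_order=orf_order,
        gc_per_orf=gc_ring,
        presence=presence,
        forward_ring=fwd,
        reverse_ring=rev,
        orf_positions=positions,
        contig_ring=contig_ring,
        homolog_count=homolog_count,
    )
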