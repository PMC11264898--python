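"""Orthogroups, presence matrices and pairwise protein identity.

Orthology for real data sets is inferred by a dedicated external tool whose
tab-separated assignment table is ingested by :func:`read_orthogroup_table`
(Orthofinder ``Orthogroups.tsv`` dialect).  For self-contained, desk-scale
runs the package ships a classical reciprocal-best-hit (RBH) inference:
all-against-all local alignments between genomes, best hit per query above
identity/coverage thresholds, reciprocal pairs form edges, and orthogroups
are the connected components of the resulting graph.  This is a test-scale
substitute, not a re-implementation of the external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqRecord import SeqRecord

from .ingest import GenomeRecord

__all__ = [
    "OrthogroupSet",
    "PresenceMatrix",
    "IdentityRecord",
    "read_orthogroup_table",
    "infer_orthogroups",
    "presence_matrix",
    "pairwise_identity",
]

GeneRef = tuple[str, str]  # (genome_id, locus_tag)


@dataclass
class OrthogroupSet:
    """Partition of genes into orthogroups.

    ``groups`` maps og_id -> list of (genome_id, locus_tag).  Every gene
    occurs in at most one group.  ``singletons_added`` records whether genes
    missing from an external assignment table were appended as singleton
    groups.
    """

    groups: dict[str, list[GeneRef]] = field(default_factory=dict)
    singletons_added: bool = False

    def __post_init__(self) -> None:
        seen: dict[GeneRef, str] = {}
        for og, members in self.groups.items():
            for ref in members:
                if ref in seen:
                    raise ValueError(
                        f"gene {ref[1]!r} of genome {ref[0]!r} assigned to both "
                        f"{seen[ref]!r} and {og!r}"
                    )
                seen[ref] = og

    def group_of(self, genome_id: str, locus_tag: str) -> str | None:
        for og, members in self.groups.items():
            if (genome_id, locus_tag) in members:
                return og
        return None

    def membership(self) -> dict[GeneRef, str]:
        return {ref: og for og, members in self.groups.items() for ref in members}

    @property
    def n_genes(self) -> int:
        return sum(len(m) for m in self.groups.values())


@dataclass
class PresenceMatrix:
    """Orthogroup x genome copy-number matrix (integer counts >= 0)."""

    df: pd.DataFrame  # rows og_id, columns genome_id

    @property
    def og_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean presence (copy number >= 1)."""
        return self.df >= 1

    def multicopy_ogs(self) -> list[str]:
        """Orthogroups with more than one copy in at least one genome."""
        return list(self.df.index[(self.df > 1).any(axis=1)])


@dataclass(frozen=True)
class IdentityRecord:
    locus_a: str
    locus_b: str
    identity: float  # percent, [0, 100]


def read_orthogroup_table(
    path: str | Path, genomes: Sequence[GenomeRecord]
) -> OrthogroupSet:
    """Read an external orthogroup assignment table.

    Format: tab-separated, first column the orthogroup id, one column per
    genome (header = genome_id), cells comma(+space)-separated locus tags.
    Genes of the input genomes absent from the table become singleton groups.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = table.columns[0]
    known = {g.genome_id: g for g in genomes}
    for col in table.columns[1:]:
        if col not in known:
            raise ValueError(f"unknown genome column {col!r} in {path}")

    valid_refs = {
        (g.genome_id, f.locus_tag) for g in genomes for f in g.features
    }
    groups: dict[str, list[GeneRef]] = {}
    seen: dict[GeneRef, str] = {}
    for _, row in table.iterrows():
        og = row[og_col]
        members: list[GeneRef] = []
        for col in table.columns[1:]:
            cell = row[col].strip()
            if not cell:
                continue
            for tag in (t.strip() for t in cell.split(",")):
                if not tag:
                    continue
                ref = (col, tag)
                if ref not in valid_refs:
                    raise ValueError(
                        f"locus {tag!r} (genome {col!r}) in {path} does not "
                        "exist in the parsed genomes"
                    )
                if ref in seen:
                    raise ValueError(
                        f"locus {tag!r} assigned to both {seen[ref]!r} and {og!r}"
                    )
                seen[ref] = og
                members.append(ref)
        groups[og] = members

    # genes not covered by the table -> singleton groups, deterministic order
    missing = sorted(valid_refs - set(seen))
    for i, ref in enumerate(missing):
        groups[f"OG_single_{i:05d}"] = [ref]
    return OrthogroupSet(groups=groups, singletons_added=bool(missing))


# --- built-in RBH inference -------------------------------------------------

def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _column_stats(alignment) -> tuple[int, int]:
    """(identical columns, columns with a residue on both sides)."""
    a, b = alignment[0], alignment[1]
    ident = cols = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            ident += 1
    return ident, cols


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def infer_orthogroups(
    proteomes: Mapping[str, Sequence[SeqRecord]],
    min_identity: float = 30.0,
    min_coverage: float = 0.5,
) -> OrthogroupSet:
    """Desk-scale reciprocal-best-hit orthology over per-genome proteomes.

    For each ordered genome pair, the best local-alignment hit per query
    (BLOSUM62, gap open 11 / extend 1) passing ``min_identity`` (percent,
    over aligned residue columns) and ``min_coverage`` (aligned residue
    columns / length of the shorter sequence) is retained; reciprocal best
    hits form edges and orthogroups are the connected components.  Genes
    with no edge become singletons.  Ties on score break lexicographically
    by locus tag, making the result deterministic and independent of genome
    input order.
    """
    if not (0.0 <= min_identity <= 100.0):
        raise ValueError(f"min_identity must be in [0, 100], got {min_identity}")
    if not (0.0 <= min_coverage <= 1.0):
        raise ValueError(f"min_coverage must be in [0, 1], got {min_coverage}")
    genome_ids = sorted(proteomes)
    if len(genome_ids) < 2:
        raise ValueError("RBH inference needs at least two genomes")
    seqs: dict[GeneRef, str] = {}
    for gid in genome_ids:
        for rec in proteomes[gid]:
            seqs[(gid, rec.id)] = str(rec.seq)

    aligner = _local_aligner()
    best: dict[tuple[GeneRef, str], GeneRef] = {}  # (query, target genome) -> hit
    for ga in genome_ids:
        for gb in genome_ids:
            if ga == gb:
                continue
            targets = sorted(rec.id for rec in proteomes[gb])
            for qrec in proteomes[ga]:
                q = str(qrec.seq)
                if not q:
                    continue
                top: tuple[float, str] | None = None
                for ttag in targets:
                    t = seqs[(gb, ttag)]
                    if not t:
                        continue
                    alns = aligner.align(q, t)
                    if len(alns) == 0:
                        continue
                    aln = alns[0]
                    ident, cols = _column_stats(aln)
                    if cols == 0:
                        continue
                    pid = 100.0 * ident / cols
                    cov = cols / min(len(q), len(t))
                    if pid < min_identity or cov < min_coverage:
                        continue
                    score = aln.score
                    if top is None or score > top[0] or (score == top[0] and ttag < top[1]):
                        top = (score, ttag)
                if top is not None:
                    best[((ga, qrec.id), gb)] = (gb, top[1])

    uf = _UnionFind()
    for ref in seqs:
        uf.find(ref)
    for (query, _tg), hit in best.items():
        back = best.get((hit, query[0]))
        if back == query:
            uf.union(query, hit)

    components: dict[GeneRef, list[GeneRef]] = {}
    for ref in seqs:
        components.setdefault(uf.find(ref), []).append(ref)
    ordered = sorted(sorted(members) for members in components.values())
    groups = {f"OG{i:07d}": members for i, members in enumerate(ordered)}
    return OrthogroupSet(groups=groups)


def presence_matrix(
    ogset: OrthogroupSet, genomes: Sequence[str]
) -> PresenceMatrix:
    """Copy-number matrix: cell (og, genome) = members of og from genome."""
    genome_ids = list(genomes)
    known = set(genome_ids)
    og_ids = sorted(ogset.groups)
    df = pd.DataFrame(0, index=og_ids, columns=genome_ids, dtype=int)
    for og, members in ogset.groups.items():
        for gid, _tag in members:
            if gid not in known:
                raise ValueError(f"orthogroup {og!r} references unknown genome {gid!r}")
            df.loc[og, gid] += 1
    return PresenceMatrix(df=df)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent amino-acid identity from a global alignment.

    Identity = 100 * identical residue pairs / aligned columns where neither
    side is a gap (terminal and internal gap columns excluded from the
    denominator).  Symmetric by construction (the pair is canonically
    ordered before aligning); 0.0 when no residue column aligns.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aln = _global_aligner().align(seq_a, seq_b)[0]
    ident, cols = _column_stats(aln)
    if cols == 0:
        return 0.0
    return 100.0 * ident / cols


def identity_records(
    pairs: Iterable[tuple[str, str, str, str]],
    sequences: Mapping[GeneRef, str],
) -> list[IdentityRecord]:
    """Compute IdentityRecords for (genome_a, locus_a, genome_b, locus_b) pairs."""
    out = []
    for ga, la, gb, lb in pairs:
        pid = pairwise_identity(sequences[(ga, la)], sequences[(gb, lb)])
        out.append(IdentityRecord(locus_a=la, locus_b=lb, identity=pid))
    return out
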