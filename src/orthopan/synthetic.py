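"""Synthetic annotated bacterial genomes with known ground truth.

The generator plants a set of ancestral protein families and evolves one
genome per taxon by per-residue substitution, gene loss, duplication and
pseudogenization.  Proteins are back-translated with a fixed codon per amino
acid (translation table 11), laid out on a single contig per genome with
fixed spacers, and written as GenBank flat files.  Alongside the genomes the
generator emits the complete truth: the planted orthogroup table
(assignment-table dialect), KO and COG annotation tables, KEGG-style module
definitions with per-genome expected completeness (computed by an evaluator
independent of the scoring module), and per-genome summary bookkeeping.

Everything is deterministic given the seed.  What a green test on these
fixtures does and does not establish is discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = ["FixtureConfig", "FixtureTruth", "GeneTruth", "generate_fixture",
           "random_module_definition"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one fixed codon per amino acid (table 11); deterministic back-translation
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}
_STOP = "TAA"
_SPACER = ("ACGT" * 25)  # 100 bp fixed-composition spacer


def _conservative_exchanges() -> dict[str, list[str]]:
    """For each amino acid, the substitutes with a positive BLOSUM62 score
    (falling back to the best-scoring ones) — keeps mutated proteins alignable."""
    m = substitution_matrices.load("BLOSUM62")
    out: dict[str, list[str]] = {}
    for a in AMINO_ACIDS:
        scored = sorted(
            ((m[a, b], b) for b in AMINO_ACIDS if b != a), reverse=True
        )
        positive = [b for s, b in scored if s > 0]
        out[a] = positive if positive else [b for _, b in scored[:3]]
    return out


@dataclass
class FixtureConfig:
    """Stated world for the generator.

    Defaults describe a small panel of closely related bacterial isolates:
    6 genomes, 30 gene families of 60-150 aa, 5% per-branch substitution
    probability, 5% duplication, 10% loss, 5% pseudogenization, 3 metabolic
    modules over the planted KOs, and a 20% chance for any gene to lack its
    direct KO annotation (the propagation cases).
    """

    n_genomes: int = 6
    n_families: int = 30
    divergence: float = 0.05  # per-residue substitution probability per genome
    paralog_rate: float = 0.05
    loss_rate: float = 0.10
    pseudogene_rate: float = 0.05
    n_modules: int = 3
    ko_dropout: float = 0.20  # probability a gene lacks its direct KO
    min_protein_len: int = 60
    max_protein_len: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "paralog_rate", "loss_rate",
                     "pseudogene_rate", "ko_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genomes < 1 or self.n_families < 1:
            raise ValueError("need at least one genome and one family")


@dataclass(frozen=True)
class GeneTruth:
    genome_id: str
    locus_tag: str
    family: int
    is_pseudo: bool
    has_direct_ko: bool
    protein: str


@dataclass
class FixtureTruth:
    config: FixtureConfig
    genes: list[GeneTruth]
    orthogroups: dict[str, list[tuple[str, str]]]  # og -> [(genome, locus)]
    ko_of_family: dict[int, str]
    cog_of_family: dict[int, tuple[str, str]]  # family -> (cog id, category)
    modules: dict[str, str]  # module_id -> definition string
    expected_completeness: dict[tuple[str, str], tuple[float, float]]
    # (module_id, genome_id) -> (direct-only, with propagation)
    summaries: dict[str, dict] = field(default_factory=dict)

    def genome_ids(self) -> list[str]:
        return sorted({g.genome_id for g in self.genes})

    def occupancy_counts(self) -> dict[int, int]:
        """Occupancy spectrum of the planted orthogroups (presence >= 1)."""
        counts: dict[int, int] = {}
        for members in self.orthogroups.values():
            j = len({g for g, _ in members})
            counts[j] = counts.get(j, 0) + 1
        return counts


# --- independent module evaluator (construction-side) -------------------------
# The generator builds modules from an explicit structure, so expected
# completeness is computed directly on that structure — never through the
# scoring module's parser or evaluator.

_Struct = tuple  # ("atom", ko) | ("steps", [..]) | ("alt", [..]) | ("complex", [(ko, optional)])


def _struct_value(struct: _Struct, kos: set[str]) -> float:
    kind = struct[0]
    if kind == "atom":
        return 1.0 if struct[1] in kos else 0.0
    if kind == "steps":
        vals = [_struct_value(s, kos) for s in struct[1]]
        return sum(vals) / len(vals)
    if kind == "alt":
        return max(_struct_value(s, kos) for s in struct[1])
    if kind == "complex":
        return 1.0 if all(
            struct_ko in kos or optional for struct_ko, optional in struct[1]
        ) else 0.0
    raise ValueError(kind)


def _struct_text(struct: _Struct) -> str:
    kind = struct[0]
    if kind == "atom":
        return struct[1]
    if kind == "steps":
        return " ".join(
            f"({_struct_text(s)})" if s[0] in ("steps",) else _struct_text(s)
            for s in struct[1]
        )
    if kind == "alt":
        return ",".join(
            f"({_struct_text(s)})" if s[0] in ("steps", "alt") else _struct_text(s)
            for s in struct[1]
        )
    if kind == "complex":
        parts = []
        for i, (ko, optional) in enumerate(struct[1]):
            if optional:
                parts.append(f"-{ko}")
            elif i > 0:
                parts.append(f"+{ko}")
            else:
                parts.append(ko)
        return "".join(parts)
    raise ValueError(kind)


def _build_modules(
    kos: Sequence[str], n_modules: int, rng: np.random.Generator
) -> dict[str, _Struct]:
    """Modules mixing steps, alternatives and complexes over the planted KOs."""
    modules: dict[str, _Struct] = {}
    pool = list(kos)
    for i in range(n_modules):
        rng.shuffle(pool)
        take = pool[: min(len(pool), 5)]
        steps: list[_Struct] = []
        j = 0
        while j < len(take):
            style = int(rng.integers(0, 3))
            if style == 1 and j + 1 < len(take):  # OR alternative
                steps.append(("alt", [("atom", take[j]), ("atom", take[j + 1])]))
                j += 2
            elif style == 2 and j + 1 < len(take):  # complex, second subunit optional half the time
                optional = bool(rng.integers(0, 2))
                steps.append(("complex", [(take[j], False), (take[j + 1], optional)]))
                j += 2
            else:
                steps.append(("atom", take[j]))
                j += 1
        modules[f"M{90001 + i:05d}"] = ("steps", steps) if len(steps) > 1 else steps[0]
    return modules


def random_module_definition(
    rng: np.random.Generator, max_atoms: int = 6, _depth: int = 0
) -> str:
    """A random well-formed module definition with <= max_atoms distinct KOs
    (for parser round-trip and oracle-equivalence tests)."""
    kos = [f"K{int(rng.integers(1, 100)):05d}" for _ in range(max_atoms)]

    def expr(depth: int) -> str:
        choice = int(rng.integers(0, 4 if depth < 2 else 1))
        if choice == 0:  # atom or gap
            return "--" if rng.random() < 0.1 else str(rng.choice(kos))
        if choice == 1:  # steps
            n = int(rng.integers(2, 4))
            return " ".join(_wrap(expr(depth + 1)) for _ in range(n))
        if choice == 2:  # alternatives
            n = int(rng.integers(2, 4))
            return ",".join(_wrap(expr(depth + 1)) for _ in range(n))
        # complex over atoms only
        n = int(rng.integers(2, 4))
        parts = [str(rng.choice(kos))]
        for _ in range(n - 1):
            op = "-" if rng.random() < 0.3 else "+"
            parts.append(op + str(rng.choice(kos)))
        return "".join(parts)

    def _wrap(s: str) -> str:
        return f"({s})" if (" " in s or "," in s) else s

    return expr(0)


# --- genome construction -------------------------------------------------------

def generate_fixture(
    config: FixtureConfig, out_dir: str | Path | None = None
) -> tuple[dict[str, Path], FixtureTruth]:
    """Generate GenBank genomes plus truth tables.

    Returns (genome_id -> GenBank path, FixtureTruth).  When ``out_dir`` is
    None the files go to nothing — pass a directory to materialise them; the
    truth object is always returned.  Also writes, when ``out_dir`` is given:
    ``orthogroups.tsv``, ``ko.tsv``, ``cog.tsv``, ``modules.tsv``,
    ``expected_completeness.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    exchanges = _conservative_exchanges()

    lengths = rng.integers(
        config.min_protein_len, config.max_protein_len + 1, size=config.n_families
    )
    ancestors = [
        "M" + "".join(rng.choice(list(AMINO_ACIDS), size=int(n) - 1))
        for n in lengths
    ]

    genome_ids = [f"g{i + 1}" for i in range(config.n_genomes)]
    ko_of_family = {
        f: f"K{f + 1:05d}" for f in range(config.n_families)
    }
    cog_cats = "JKLDMNOCGEFHIP"
    cog_of_family = {
        f: (f"COG{f + 1:04d}", cog_cats[f % len(cog_cats)])
        for f in range(config.n_families)
    }

    def mutate(protein: str) -> str:
        out = list(protein)
        for i in range(1, len(out)):  # keep the start Met
            if rng.random() < config.divergence:
                out[i] = str(rng.choice(exchanges[out[i]]))
        return "".join(out)

    genes: list[GeneTruth] = []
    orthogroups: dict[str, list[tuple[str, str]]] = {
        f"OG{f:07d}": [] for f in range(config.n_families)
    }
    records: dict[str, SeqRecord] = {}

    for gid in genome_ids:
        gene_rows: list[tuple[int, str, bool, bool]] = []  # family, protein, pseudo, has_ko
        for fam in range(config.n_families):
            if rng.random() < config.loss_rate:
                continue
            n_copies = 1 + (1 if rng.random() < config.paralog_rate else 0)
            for _copy in range(n_copies):
                protein = mutate(ancestors[fam])
                pseudo = rng.random() < config.pseudogene_rate
                has_ko = (not pseudo) and rng.random() >= config.ko_dropout
                gene_rows.append((fam, protein, pseudo, has_ko))

        seq_parts: list[str] = [_SPACER]
        features: list[SeqFeature] = []
        pos = len(_SPACER)
        for idx, (fam, protein, pseudo, has_ko) in enumerate(gene_rows):
            tag = f"{gid.upper()}_{idx + 1:04d}"
            nuc = "".join(_CODON[a] for a in protein) + _STOP
            strand = 1 if rng.random() < 0.5 else -1
            gene_nuc = nuc if strand == 1 else str(Seq(nuc).reverse_complement())
            start, end = pos, pos + len(nuc)
            quals = {
                "locus_tag": [tag],
                "product": [f"family {fam} protein"],
                "transl_table": ["11"],
            }
            if pseudo:
                quals["pseudo"] = [""]
            else:
                quals["translation"] = [protein]
            features.append(
                SeqFeature(
                    FeatureLocation(start, end, strand=strand),
                    type="CDS",
                    qualifiers=quals,
                )
            )
            seq_parts.append(gene_nuc)
            seq_parts.append(_SPACER)
            pos = end + len(_SPACER)
            genes.append(
                GeneTruth(
                    genome_id=gid, locus_tag=tag, family=fam,
                    is_pseudo=pseudo, has_direct_ko=has_ko, protein=protein,
                )
            )
            orthogroups[f"OG{fam:07d}"].append((gid, tag))

        seq = "".join(seq_parts)
        rec = SeqRecord(
            Seq(seq),
            id=f"{gid}_contig1",
            name=f"{gid}_contig1"[:16],
            description=f"synthetic genome {gid}",
            annotations={"molecule_type": "DNA", "organism": f"Synthetica fixturensis {gid}"},
        )
        rec.features = [
            SeqFeature(FeatureLocation(0, len(seq)), type="source")
        ] + features
        records[gid] = rec

    orthogroups = {og: m for og, m in orthogroups.items() if m}

    # expected module completeness via the construction-side evaluator
    structs = _build_modules(
        [ko_of_family[f] for f in sorted(ko_of_family)], config.n_modules,
        np.random.default_rng(config.seed + 1),
    )
    modules = {mid: _struct_text(s) for mid, s in structs.items()}
    expected: dict[tuple[str, str], tuple[float, float]] = {}
    for gid in genome_ids:
        direct = {
            ko_of_family[g.family]
            for g in genes
            if g.genome_id == gid and g.has_direct_ko
        }
        # propagation closure: a genome's gene gains the family KO if any
        # member of the family (any genome) is directly annotated
        # any gene of the genome (pseudogenes included: they sit in the
        # orthogroup and receive the propagated KO like any other member)
        families_here = {g.family for g in genes if g.genome_id == gid}
        annotated_families = {
            g.family for g in genes if g.has_direct_ko
        }
        propagated = direct | {
            ko_of_family[f] for f in families_here & annotated_families
        }
        for mid, s in structs.items():
            expected[(mid, gid)] = (
                _struct_value(s, direct),
                _struct_value(s, propagated),
            )

    # per-genome bookkeeping
    summaries: dict[str, dict] = {}
    for gid in genome_ids:
        seq = str(records[gid].seq)
        n_cds = sum(
            1 for g in genes if g.genome_id == gid
        )
        gc = seq.count("G") + seq.count("C")
        summaries[gid] = {
            "total_length": len(seq),
            "gc_percent": 100.0 * gc / len(seq),
            "n_contigs": 1,
            "n_cds": sum(
                1 for g in genes if g.genome_id == gid and not g.is_pseudo
            ),
            "n_genes": n_cds,
        }

    truth = FixtureTruth(
        config=config,
        genes=genes,
        orthogroups=orthogroups,
        ko_of_family=ko_of_family,
        cog_of_family=cog_of_family,
        modules=modules,
        expected_completeness=expected,
        summaries=summaries,
    )

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid, rec in records.items():
            p = out / f"{gid}.gbk"
            SeqIO.write([rec], str(p), "genbank")
            paths[gid] = p
        _write_truth_tables(out, truth, genome_ids)
    return paths, truth


def _write_truth_tables(
    out: Path, truth: FixtureTruth, genome_ids: Sequence[str]
) -> None:
    # orthogroup assignment table (tabular dialect: cells comma+space separated)
    lines = ["Orthogroup\t" + "\t".join(genome_ids)]
    for og in sorted(truth.orthogroups):
        cells = []
        for gid in genome_ids:
            tags = sorted(t for g, t in truth.orthogroups[og] if g == gid)
            cells.append(", ".join(tags))
        lines.append(og + "\t" + "\t".join(cells))
    (out / "orthogroups.tsv").write_text("\n".join(lines) + "\n")

    ko_lines = [
        f"{g.genome_id}\t{g.locus_tag}\t{truth.ko_of_family[g.family]}"
        for g in truth.genes
        if g.has_direct_ko
    ]
    (out / "ko.tsv").write_text("\n".join(ko_lines) + ("\n" if ko_lines else ""))

    cog_lines = []
    for g in truth.genes:
        if g.is_pseudo:
            continue
        cid, cat = truth.cog_of_family[g.family]
        cog_lines.append(f"{g.genome_id}\t{g.locus_tag}\t{cid}\t{cat}\tcategory {cat}")
    (out / "cog.tsv").write_text("\n".join(cog_lines) + ("\n" if cog_lines else ""))

    (out / "modules.tsv").write_text(
        "".join(f"{mid}\t{text}\n" for mid, text in sorted(truth.modules.items()))
    )

    comp_lines = ["module_id\tgenome_id\tdirect\tpropagated"]
    for (mid, gid), (d, p) in sorted(truth.expected_completeness.items()):
        comp_lines.append(f"{mid}\t{gid}\t{d:.6f}\t{p:.6f}")
    (out / "expected_completeness.tsv").write_text("\n".join(comp_lines) + "\n")
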