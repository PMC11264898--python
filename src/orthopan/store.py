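"""Relational result store, portable archives and pipeline orchestration.

All computed results live in a single SQLite file: genomes, contigs, genes,
orthogroups and memberships, pairwise identities, annotations (KO/COG/Pfam
and other key/value annotations with provenance), module definitions and
completeness, trees (Newick text) and run metadata (tool version, schema
version, seeds and every default parameter) — so any figure-quality output
is reproducible from the store alone.  Optional analyses that were not run
leave their tables empty and are flagged in the metadata.

A store can be exported as a gzip-compressed tar archive holding the
database and a manifest (schema version, tool version, SHA-256 checksum);
import verifies both before extracting.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
import tarfile
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import kegg, orthology, pangenome, phylo, regions, search
from .ingest import GenomeRecord, extract_sequences, genome_summary, parse_genbank, sanitize_identifiers
from .kegg import CompletenessMatrix, KoAssignment, ModuleDefinition
from .orthology import OrthogroupSet, PresenceMatrix
from .profiles import CategoryAnnotation

__all__ = [
    "SCHEMA_VERSION",
    "ResultStore",
    "build_store",
    "open_store",
    "export_archive",
    "import_archive",
    "run_pipeline",
]

SCHEMA_VERSION = 1
TOOL_VERSION = "0.1.0"

_SCHEMA = """
PRAGMA foreign_keys = ON;
CREATE TABLE genomes (
    genome_id TEXT PRIMARY KEY,
    display_name TEXT NOT NULL,
    total_length INTEGER, gc_percent REAL, n_contigs INTEGER,
    n_cds INTEGER, coding_density REAL
);
CREATE TABLE contigs (
    accession TEXT PRIMARY KEY,
    genome_id TEXT NOT NULL REFERENCES genomes(genome_id),
    length INTEGER NOT NULL,
    sequence TEXT NOT NULL
);
CREATE TABLE genes (
    genome_id TEXT NOT NULL REFERENCES genomes(genome_id),
    locus_tag TEXT PRIMARY KEY,
    contig TEXT NOT NULL REFERENCES contigs(accession),
    start INTEGER NOT NULL, end INTEGER NOT NULL, strand INTEGER NOT NULL,
    feature_kind TEXT NOT NULL,
    gene_name TEXT, product TEXT,
    protein_seq TEXT, nucleotide_seq TEXT NOT NULL
);
CREATE TABLE orthogroups (og_id TEXT PRIMARY KEY);
CREATE TABLE gene_orthogroup (
    og_id TEXT NOT NULL REFERENCES orthogroups(og_id),
    genome_id TEXT NOT NULL REFERENCES genomes(genome_id),
    locus_tag TEXT NOT NULL REFERENCES genes(locus_tag),
    UNIQUE (genome_id, locus_tag)
);
CREATE TABLE identities (
    locus_a TEXT NOT NULL REFERENCES genes(locus_tag),
    locus_b TEXT NOT NULL REFERENCES genes(locus_tag),
    identity REAL NOT NULL CHECK (identity >= 0 AND identity <= 100)
);
CREATE TABLE annotations (
    genome_id TEXT NOT NULL REFERENCES genomes(genome_id),
    locus_tag TEXT NOT NULL REFERENCES genes(locus_tag),
    type TEXT NOT NULL,       -- ko | cog | pfam | ...
    key TEXT NOT NULL,        -- annotation id
    value TEXT,               -- e.g. category code
    provenance TEXT NOT NULL DEFAULT 'direct'
);
CREATE TABLE module_definitions (
    module_id TEXT PRIMARY KEY,
    definition TEXT NOT NULL
);
CREATE TABLE completeness (
    module_id TEXT NOT NULL REFERENCES module_definitions(module_id),
    genome_id TEXT NOT NULL REFERENCES genomes(genome_id),
    completeness REAL NOT NULL,
    used_propagated INTEGER NOT NULL,
    satisfied_atoms TEXT NOT NULL
);
CREATE TABLE trees (
    name TEXT PRIMARY KEY,
    newick TEXT NOT NULL
);
CREATE TABLE run_metadata (key TEXT PRIMARY KEY, value TEXT NOT NULL);
"""


@dataclass
class ResultStore:
    """Handle over the SQLite result database."""

    path: Path

    def connect(self) -> sqlite3.Connection:
        conn = sqlite3.connect(self.path)
        conn.execute("PRAGMA foreign_keys = ON")
        return conn

    # -- reading back ----------------------------------------------------------

    def metadata(self) -> dict[str, str]:
        with self.connect() as conn:
            return dict(conn.execute("SELECT key, value FROM run_metadata"))

    def table_rowsets(self) -> dict[str, frozenset]:
        """Every table as a frozen set of rows (for round-trip comparison)."""
        with self.connect() as conn:
            tables = [
                r[0]
                for r in conn.execute(
                    "SELECT name FROM sqlite_master WHERE type='table'"
                )
            ]
            return {
                t: frozenset(map(tuple, conn.execute(f"SELECT * FROM {t}")))
                for t in tables
            }

    def genomes(self) -> list[GenomeRecord]:
        from .ingest import ContigRecord, GeneFeature

        with self.connect() as conn:
            out = []
            for gid, name in conn.execute(
                "SELECT genome_id, display_name FROM genomes ORDER BY genome_id"
            ):
                contigs = [
                    ContigRecord(accession=acc, sequence=seq)
                    for acc, seq in conn.execute(
                        "SELECT accession, sequence FROM contigs WHERE genome_id=? "
                        "ORDER BY rowid",
                        (gid,),
                    )
                ]
                feats = [
                    GeneFeature(
                        locus_tag=row[0], contig=row[1], start=row[2], end=row[3],
                        strand=row[4], feature_kind=row[5], gene_name=row[6],
                        product=row[7], protein_seq=row[8], nucleotide_seq=row[9],
                    )
                    for row in conn.execute(
                        "SELECT locus_tag, contig, start, end, strand, feature_kind,"
                        " gene_name, product, protein_seq, nucleotide_seq"
                        " FROM genes WHERE genome_id=? ORDER BY contig, start, locus_tag",
                        (gid,),
                    )
                ]
                out.append(
                    GenomeRecord(
                        genome_id=gid, display_name=name, contigs=contigs,
                        features=feats,
                    )
                )
            return out

    def orthogroups(self) -> OrthogroupSet:
        with self.connect() as conn:
            groups: dict[str, list[tuple[str, str]]] = {
                og: [] for (og,) in conn.execute("SELECT og_id FROM orthogroups")
            }
            for og, gid, tag in conn.execute(
                "SELECT og_id, genome_id, locus_tag FROM gene_orthogroup "
                "ORDER BY og_id, genome_id, locus_tag"
            ):
                groups[og].append((gid, tag))
        return OrthogroupSet(groups=groups)

    def presence_matrix(self) -> PresenceMatrix:
        with self.connect() as conn:
            genome_ids = [g for (g,) in conn.execute(
                "SELECT genome_id FROM genomes ORDER BY genome_id"
            )]
        return orthology.presence_matrix(self.orthogroups(), genome_ids)

    def ko_assignment(self, include_propagated: bool = True) -> KoAssignment:
        with self.connect() as conn:
            rows = conn.execute(
                "SELECT genome_id, locus_tag, key, provenance, value FROM annotations "
                "WHERE type='ko' ORDER BY genome_id, locus_tag, key"
            ).fetchall()
        entries = [
            kegg.KoEntry(
                genome_id=g, locus_tag=t, ko=k, provenance=p,
                source_orthogroup=(v or None) if p == "propagated" else None,
            )
            for g, t, k, p, v in rows
            if include_propagated or p == "direct"
        ]
        return KoAssignment(entries=entries)

    def module_definitions(self) -> list[ModuleDefinition]:
        with self.connect() as conn:
            rows = conn.execute(
                "SELECT module_id, definition FROM module_definitions ORDER BY module_id"
            ).fetchall()
        return [kegg.parse_module_definition(d, module_id=m) for m, d in rows]

    def tree(self, name: str = "species") -> str:
        with self.connect() as conn:
            row = conn.execute("SELECT newick FROM trees WHERE name=?", (name,)).fetchone()
        if row is None:
            raise KeyError(f"no tree named {name!r} in store")
        return row[0]

    # -- canned queries (the query surface of the tool) ------------------------

    def occupancy_spectrum(self) -> pangenome.OccupancySpectrum:
        return pangenome.occupancy_spectrum(self.presence_matrix())

    def differential_query(self, include, exclude=()) -> list[str]:
        return pangenome.differential_query(self.presence_matrix(), include, exclude)

    def completeness_matrix(self, use_propagated: bool = True) -> CompletenessMatrix:
        return kegg.completeness_matrix(
            self.module_definitions(),
            self.ko_assignment(include_propagated=use_propagated),
            [g.genome_id for g in self.genomes()],
            use_propagated=use_propagated,
        )

    def search(self, expression: str) -> str:
        """Search-bar query over the stored genes; TSV of hits."""
        genomes = self.genomes()
        with self.connect() as conn:
            triples: dict[str, list[tuple[str, str, str]]] = {}
            for gid, tag, typ, key in conn.execute(
                "SELECT genome_id, locus_tag, type, key FROM annotations"
            ):
                triples.setdefault(typ, []).append((gid, tag, key))
        index = search.build_index(genomes, annotations=triples)
        return search.hits_to_tsv(search.execute_query(search.parse_query(expression), index))

    def region_comparison(self, anchor_genome: str, anchor_locus: str,
                          window_bp: int = regions.DEFAULT_WINDOW_BP) -> regions.RegionComparison:
        genomes = {g.genome_id: g for g in self.genomes()}
        return regions.compare_regions(
            genomes, anchor_genome, anchor_locus, self.orthogroups(),
            window_bp=window_bp,
        )

    def circos_tracks(self, reference: str,
                      comparison: Sequence[str] | None = None) -> regions.TrackSet:
        genomes = {g.genome_id: g for g in self.genomes()}
        if comparison is None:
            comparison = [g for g in genomes if g != reference]
        return regions.circos_tracks(
            genomes[reference], [genomes[g] for g in comparison], self.orthogroups()
        )


def build_store(
    path: str | Path,
    genomes: Sequence[GenomeRecord],
    ogset: OrthogroupSet | None = None,
    identities: Sequence[orthology.IdentityRecord] = (),
    ko_assignments: KoAssignment | None = None,
    categories: CategoryAnnotation | None = None,
    module_definitions: Sequence[ModuleDefinition] = (),
    completeness: CompletenessMatrix | None = None,
    trees: Mapping[str, str] | None = None,
    parameters: Mapping[str, object] | None = None,
) -> ResultStore:
    """Write all supplied results into a fresh SQLite store.

    Only genomes are mandatory; absent optional analyses leave their tables
    empty and are flagged in ``run_metadata``.  Foreign-key integrity is
    enforced; a violation aborts naming the offending record.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    try:
        conn.executescript(_SCHEMA)
        for g in genomes:
            s = genome_summary(g)
            conn.execute(
                "INSERT INTO genomes VALUES (?,?,?,?,?,?,?)",
                (g.genome_id, g.display_name, s.total_length, s.gc_percent,
                 s.n_contigs, s.n_cds, s.coding_density),
            )
            for c in g.contigs:
                conn.execute(
                    "INSERT INTO contigs VALUES (?,?,?,?)",
                    (c.accession, g.genome_id, c.length, c.sequence),
                )
            for f in g.features:
                conn.execute(
                    "INSERT INTO genes VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                    (g.genome_id, f.locus_tag, f.contig, f.start, f.end,
                     f.strand, f.feature_kind, f.gene_name, f.product,
                     f.protein_seq, f.nucleotide_seq),
                )
        if ogset is not None:
            for og in sorted(ogset.groups):
                conn.execute("INSERT INTO orthogroups VALUES (?)", (og,))
                for gid, tag in sorted(ogset.groups[og]):
                    conn.execute(
                        "INSERT INTO gene_orthogroup VALUES (?,?,?)", (og, gid, tag)
                    )
        for rec in identities:
            conn.execute(
                "INSERT INTO identities VALUES (?,?,?)",
                (rec.locus_a, rec.locus_b, rec.identity),
            )
        if ko_assignments is not None:
            for e in ko_assignments.entries:
                conn.execute(
                    "INSERT INTO annotations VALUES (?,?,?,?,?,?)",
                    (e.genome_id, e.locus_tag, "ko", e.ko,
                     e.source_orthogroup, e.provenance),
                )
        if categories is not None:
            for e in categories.entries:
                conn.execute(
                    "INSERT INTO annotations VALUES (?,?,?,?,?,?)",
                    (e.genome_id, e.locus_tag, "cog", e.annotation_id,
                     e.category_code, "direct"),
                )
        for d in module_definitions:
            conn.execute(
                "INSERT INTO module_definitions VALUES (?,?)",
                (d.module_id, d.serialize()),
            )
        if completeness is not None:
            for (mid, gid), res in sorted(completeness.results.items()):
                conn.execute(
                    "INSERT INTO completeness VALUES (?,?,?,?,?)",
                    (mid, gid, res.completeness, int(res.used_propagated),
                     ",".join(sorted(res.satisfied_atoms))),
                )
        for name, newick in (trees or {}).items():
            conn.execute("INSERT INTO trees VALUES (?,?)", (name, newick))

        meta = {
            "schema_version": str(SCHEMA_VERSION),
            "tool_version": TOOL_VERSION,
            "optional_orthology": str(ogset is not None),
            "optional_ko": str(ko_assignments is not None),
            "optional_categories": str(categories is not None),
            "optional_modules": str(bool(module_definitions)),
            "optional_trees": str(bool(trees)),
        }
        for k, v in (parameters or {}).items():
            meta[f"param_{k}"] = json.dumps(v, sort_keys=True, default=str)
        for k, v in sorted(meta.items()):
            conn.execute("INSERT INTO run_metadata VALUES (?,?)", (k, v))
        conn.commit()
    except sqlite3.IntegrityError as exc:
        conn.close()
        path.unlink(missing_ok=True)
        raise ValueError(f"integrity violation while building store: {exc}") from exc
    finally:
        conn.close()
    return ResultStore(path=path)


def open_store(path: str | Path) -> ResultStore:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    store = ResultStore(path=path)
    meta = store.metadata()
    if int(meta.get("schema_version", -1)) != SCHEMA_VERSION:
        raise ValueError(
            f"store schema version {meta.get('schema_version')} is incompatible "
            f"with this build (expects {SCHEMA_VERSION})"
        )
    return store


# --- archives --------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def export_archive(store: ResultStore, archive_path: str | Path) -> Path:
    """Export the store as a gzip-compressed tar with a checksum manifest."""
    archive_path = Path(archive_path)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": TOOL_VERSION,
        "database": "results.db",
        "sha256": _sha256(store.path),
    }
    with tarfile.open(archive_path, "w:gz") as tar:
        tar.add(store.path, arcname="results.db")
        with tempfile.NamedTemporaryFile("w", suffix=".json", delete=False) as fh:
            json.dump(manifest, fh, indent=2)
            manifest_path = fh.name
        tar.add(manifest_path, arcname="manifest.json")
        Path(manifest_path).unlink()
    return archive_path


def import_archive(archive_path: str | Path, dest_db: str | Path) -> ResultStore:
    """Verify and unpack an exported archive into a store file.

    Refuses (without partial import) on checksum mismatch or a schema version
    this build does not understand.
    """
    archive_path = Path(archive_path)
    dest_db = Path(dest_db)
    try:
        with tarfile.open(archive_path, "r:gz") as tar:
            names = tar.getnames()
            if "manifest.json" not in names or "results.db" not in names:
                raise ValueError(f"archive {archive_path} is missing members")
            manifest = json.load(tar.extractfile("manifest.json"))
            if int(manifest.get("schema_version", -1)) != SCHEMA_VERSION:
                raise ValueError(
                    f"archive schema version {manifest.get('schema_version')} is "
                    f"incompatible with this build (expects {SCHEMA_VERSION})"
                )
            with tempfile.TemporaryDirectory() as td:
                tar.extract("results.db", path=td, filter="data")
                extracted = Path(td) / "results.db"
                digest = _sha256(extracted)
                if digest != manifest["sha256"]:
                    raise ValueError(
                        f"checksum mismatch in {archive_path}: manifest "
                        f"{manifest['sha256'][:12]}..., file {digest[:12]}..."
                    )
                dest_db.write_bytes(extracted.read_bytes())
    except (tarfile.TarError, EOFError, OSError) as exc:
        raise ValueError(f"cannot read archive {archive_path}: {exc}") from exc
    return ResultStore(path=dest_db)


# --- pipeline ---------------------------------------------------------------------

def run_pipeline(
    input_files: Sequence[str | Path] | str | Path,
    out_db: str | Path,
    orthogroup_table: str | Path | None = None,
    ko_table: str | Path | None = None,
    cog_table: str | Path | None = None,
    modules_table: str | Path | None = None,
    max_missing: int = 0,
    min_identity: float = 30.0,
    min_coverage: float = 0.5,
    n_orders: int = 100,
    seed: int = 42,
) -> ResultStore:
    """End-to-end run: GenBank files in, queryable result store out.

    Stages: parse + identifier sanitation; orthology (external assignment
    table if given, otherwise the built-in reciprocal-best-hit inference);
    presence matrix; relaxed single-copy core selection, concatenated
    alignment, distance matrix and NJ species tree; optional KO propagation
    and module completeness; persistence with full run metadata.
    """
    if isinstance(input_files, (str, Path)) and Path(input_files).is_dir():
        input_files = sorted(Path(input_files).glob("*.gb*"))
    elif isinstance(input_files, (str, Path)):
        input_files = [input_files]
    genomes_raw = [parse_genbank(p) for p in input_files]
    genomes, _renames = sanitize_identifiers(genomes_raw)
    genome_ids = [g.genome_id for g in genomes]

    if orthogroup_table is not None:
        ogset = orthology.read_orthogroup_table(orthogroup_table, genomes)
    else:
        proteomes = {g.genome_id: extract_sequences(g, "protein") for g in genomes}
        ogset = orthology.infer_orthogroups(
            proteomes, min_identity=min_identity, min_coverage=min_coverage
        )
    matrix = orthology.presence_matrix(ogset, genome_ids)

    # species tree from the relaxed single-copy core
    trees: dict[str, str] = {}
    proteins = {
        (g.genome_id, f.locus_tag): f.protein_seq
        for g in genomes
        for f in g.features
        if f.protein_seq
    }
    try:
        selection = phylo.select_core_orthologs(matrix, max_missing=max_missing)
    except phylo.NoCoreError:
        selection = None
    if selection is not None and len(genome_ids) >= 2:
        alignments = {}
        for og in selection.og_ids:
            seqs = {
                gid: proteins[(gid, tag)]
                for gid, tag in ogset.groups[og]
                if (gid, tag) in proteins
            }
            alignments[og] = phylo.pad_alignment(seqs)
        super_aln = phylo.concatenate_alignments(alignments, selection, genome_ids)
        dmat = phylo.distance_matrix(super_aln)
        if len(genome_ids) >= 2:
            trees["species"] = phylo.nj_tree(dmat).to_newick()

    ko = kegg.read_ko_assignments(ko_table) if ko_table else None
    if ko is not None:
        ko = kegg.propagate_annotations(ko, ogset, genomes=genomes)
    from .profiles import read_category_annotations

    categories = read_category_annotations(cog_table) if cog_table else None
    definitions = (
        kegg.read_module_definitions(modules_table) if modules_table else []
    )
    comp = None
    if definitions and ko is not None:
        comp = kegg.completeness_matrix(
            definitions, ko, genome_ids, use_propagated=True
        )

    return build_store(
        out_db,
        genomes,
        ogset=ogset,
        ko_assignments=ko,
        categories=categories,
        module_definitions=definitions,
        completeness=comp,
        trees=trees,
        parameters={
            "seed": seed,
            "n_orders": n_orders,
            "max_missing": max_missing,
            "min_identity": min_identity,
            "min_coverage": min_coverage,
            "orthology_source": "table" if orthogroup_table else "builtin_rbh",
        },
    )
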