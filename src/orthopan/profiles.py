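"""Per-genome distributions of high-level functional categories.

COG and KEGG orthologs come with one-letter (COG) or named (KEGG BRITE)
functional categories; comparing the distribution of genes over those
categories across genomes gives a quick functional fingerprint of each
organism.  A gene may carry several categories (multi-domain proteins); it
then contributes to every one of its categories but is counted once in the
per-genome denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

__all__ = ["CategoryAnnotation", "CategoryEntry", "category_distribution",
           "read_category_annotations"]

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class CategoryEntry:
    genome_id: str
    locus_tag: str
    annotation_id: str  # e.g. COG0001 or K00001
    category_code: str  # e.g. "J"
    category_label: str = ""

    def __post_init__(self) -> None:
        if not self.category_code:
            raise ValueError("category code must be non-empty")


@dataclass
class CategoryAnnotation:
    entries: list[CategoryEntry] = field(default_factory=list)


def category_distribution(
    annotations: CategoryAnnotation,
    genome_gene_counts: Mapping[str, int],
    normalize: Literal["counts", "proportion_of_genes"] = "counts",
    denominator: Literal["all_genes", "annotated_genes"] = "all_genes",
) -> pd.DataFrame:
    """Category x genome matrix of gene counts or proportions.

    ``genome_gene_counts`` maps genome_id -> total number of genes (the
    proportion denominator in ``all_genes`` mode).  In proportion mode an
    explicit ``unannotated`` row accounts for genes carrying no category, so
    that unannotated + annotated (each gene counted once) covers every gene;
    multi-category genes make the per-category numerators sum above that.
    """
    if normalize not in ("counts", "proportion_of_genes"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    genomes = list(genome_gene_counts)
    for e in annotations.entries:
        if e.genome_id not in genome_gene_counts:
            raise ValueError(f"annotation references unknown genome {e.genome_id!r}")

    # distinct genes per (category, genome): a gene annotated twice with the
    # same category (e.g. two domains) still counts once
    genes: dict[tuple[str, str], set[str]] = {}
    annotated: dict[str, set[str]] = {g: set() for g in genomes}
    for e in annotations.entries:
        genes.setdefault((e.category_code, e.genome_id), set()).add(e.locus_tag)
        annotated[e.genome_id].add(e.locus_tag)

    categories = sorted({c for c, _ in genes})
    df = pd.DataFrame(0.0, index=categories, columns=genomes)
    for (cat, gid), tags in genes.items():
        df.loc[cat, gid] = len(tags)

    if normalize == "counts":
        return df.astype(int)

    unannot = pd.Series(
        {
            g: genome_gene_counts[g] - len(annotated[g])
            for g in genomes
        },
        name=UNANNOTATED,
    )
    df.loc[UNANNOTATED] = unannot
    denom = pd.Series(
        {
            g: (genome_gene_counts[g] if denominator == "all_genes"
                else max(len(annotated[g]), 1))
            for g in genomes
        }
    )
    if denominator == "annotated_genes":
        df = df.drop(index=UNANNOTATED)
    return df.div(denom, axis=1)


def read_category_annotations(path: str | Path) -> CategoryAnnotation:
    """TSV (genome_id, locus_tag, annotation_id, category_code[, label])."""
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        gid, tag, aid, code = parts[:4]
        label = parts[4] if len(parts) > 4 else ""
        entries.append(
            CategoryEntry(
                genome_id=gid, locus_tag=tag, annotation_id=aid,
                category_code=code, category_label=label,
            )
        )
    return CategoryAnnotation(entries=entries)
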