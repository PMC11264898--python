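"""Core-genome species phylogeny: relaxed single-copy core selection,
alignment concatenation, pairwise distances and neighbor joining.

The species tree is built from the single-copy core: orthogroups with
exactly one member in (nearly) every genome.  Incomplete assemblies miss
genes, so the all-genomes condition can be relaxed to tolerate up to
``max_missing`` absent genomes per orthogroup; multi-copy orthogroups are
always excluded (paralogy confounds the species signal).  Per-orthogroup
protein alignments are concatenated into a super-alignment (missing genomes
padded with gaps), from which p-distances (pairwise deletion) and a
classical neighbor-joining tree are computed.  Maximum-likelihood inference
on the same super-alignment remains an external, pluggable step; the
built-in distance+NJ path exists so the species-tree contract is testable
offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import PresenceMatrix

__all__ = [
    "CoreSelection",
    "SuperAlignment",
    "PhyloTree",
    "NoCoreError",
    "select_core_orthologs",
    "concatenate_alignments",
    "distance_matrix",
    "nj_tree",
    "pad_alignment",
]


class NoCoreError(ValueError):
    pass


@dataclass
class CoreSelection:
    og_ids: list[str]
    max_missing: int
    coverage: dict[str, int]  # og -> number of genomes with exactly one copy


def select_core_orthologs(matrix: PresenceMatrix, max_missing: int = 0) -> CoreSelection:
    """Relaxed single-copy core: orthogroups single-copy wherever present and
    present in at least G - max_missing genomes."""
    G = len(matrix.genome_ids)
    if not 0 <= max_missing < G:
        raise ValueError(f"max_missing must be in [0, {G - 1}], got {max_missing}")
    df = matrix.df
    single = ~(df > 1).any(axis=1)  # no multi-copy genome
    cov = (df == 1).sum(axis=1)
    keep = df.index[single & (cov >= G - max_missing)]
    og_ids = sorted(keep)
    if not og_ids:
        raise NoCoreError(
            "no single-copy core orthogroups at max_missing="
            f"{max_missing}; relax the threshold (larger max_missing)"
        )
    return CoreSelection(
        og_ids=og_ids,
        max_missing=max_missing,
        coverage={og: int(cov[og]) for og in og_ids},
    )


@dataclass
class SuperAlignment:
    rows: dict[str, str]  # genome_id -> gapped amino-acid string
    partitions: list[tuple[str, int, int]]  # (og_id, start, end) half-open

    @property
    def length(self) -> int:
        return next(iter(self.rows.values())).__len__() if self.rows else 0

    def slice(self, og_id: str) -> dict[str, str]:
        for og, s, e in self.partitions:
            if og == og_id:
                return {g: row[s:e] for g, row in self.rows.items()}
        raise KeyError(og_id)


def pad_alignment(seqs: Mapping[str, str]) -> dict[str, str]:
    """Fallback 'aligner': pad with trailing gaps to equal length.

    Adequate only when sequences differ by substitutions (no indels), as in
    the synthetic fixtures; real data should use an external aligner.
    """
    width = max(len(s) for s in seqs.values())
    return {k: s + "-" * (width - len(s)) for k, s in seqs.items()}


def concatenate_alignments(
    alignments: Mapping[str, Mapping[str, str]],
    selection: CoreSelection,
    genomes: Sequence[str],
) -> SuperAlignment:
    """Concatenate per-orthogroup alignments into one super-alignment.

    ``alignments`` maps og_id -> {genome_id -> aligned (gapped) sequence};
    a genome missing from an orthogroup receives all-gap columns for that
    partition.  Rows must be equal length within each orthogroup.
    """
    rows = {g: [] for g in genomes}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for og in selection.og_ids:
        aln = alignments[og]
        widths = {len(s) for s in aln.values()}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment in orthogroup {og!r}: lengths {sorted(widths)}")
        width = widths.pop() if widths else 0
        for g in genomes:
            rows[g].append(aln.get(g, "-" * width))
        partitions.append((og, offset, offset + width))
        offset += width
    return SuperAlignment(
        rows={g: "".join(parts) for g, parts in rows.items()},
        partitions=partitions,
    )


def distance_matrix(alignment: SuperAlignment) -> pd.DataFrame:
    """p-distance matrix with pairwise deletion.

    d(a, b) = 1 - (identical columns / columns where neither row is a gap).
    A pair with zero comparable columns is an error (no signal).
    """
    names = sorted(alignment.rows)
    if len(names) < 2:
        raise ValueError("need at least two rows")
    arr = {g: np.frombuffer(alignment.rows[g].encode(), dtype="S1") for g in names}
    gap = np.bytes_("-")
    df = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ok = (arr[a] != gap) & (arr[b] != gap)
            n = int(ok.sum())
            if n == 0:
                raise ValueError(f"no comparable columns between {a!r} and {b!r}")
            d = 1.0 - float((arr[a][ok] == arr[b][ok]).sum()) / n
            df.loc[a, b] = df.loc[b, a] = d
    return df


# --- neighbor joining ---------------------------------------------------------

@dataclass
class _TreeNode:
    name: str | None = None
    children: list[tuple["_TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree (represented with a trifurcating root) over genome leaves."""

    root: _TreeNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(n: _TreeNode) -> None:
            if n.is_leaf():
                out.append(n.name or "")
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return sorted(out)

    def to_newick(self) -> str:
        def fmt(n: _TreeNode) -> str:
            if n.is_leaf():
                return n.name or ""
            inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in n.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between every leaf pair."""
        paths: dict[str, float] = {}
        dists: dict[tuple[str, str], float] = {}

        def walk(n: _TreeNode, acc: dict[str, float]) -> dict[str, float]:
            # returns leaf -> distance to n
            if n.is_leaf():
                return {n.name or "": 0.0}
            below: dict[str, float] = {}
            groups: list[dict[str, float]] = []
            for c, bl in n.children:
                d = {leaf: dist + bl for leaf, dist in walk(c, paths).items()}
                groups.append(d)
            for i, gi in enumerate(groups):
                for gj in groups[i + 1:]:
                    for la, da in gi.items():
                        for lb, db in gj.items():
                            key = (min(la, lb), max(la, lb))
                            dists[key] = da + db
                below = {**below, **{k: v for g in groups for k, v in g.items()}}
            return below

        walk(self.root, paths)
        names = self.leaves()
        df = pd.DataFrame(0.0, index=names, columns=names)
        for (a, b), d in dists.items():
            df.loc[a, b] = df.loc[b, a] = d
        return df


def nj_tree(distances: pd.DataFrame) -> PhyloTree:
    """Classical neighbor joining with deterministic tie-breaking.

    The pair minimising the Q criterion is joined at each step; ties break
    lexicographically on the (sorted) cluster labels.  Negative branch
    lengths are clamped to zero with the deficit moved onto the sister
    branch (total preserved), then floored at zero.  For two taxa a single
    edge split evenly at the root is returned.
    """
    if not distances.index.equals(distances.columns):
        raise ValueError("distance matrix must be square with matching labels")
    names = sorted(distances.index)
    if len(names) < 2:
        raise ValueError("need at least two taxa")
    D = {
        (a, b): float(distances.loc[a, b]) for a in names for b in names if a != b
    }
    nodes: dict[str, _TreeNode] = {n: _TreeNode(name=n) for n in names}
    active = list(names)

    if len(active) == 2:
        a, b = active
        half = D[(a, b)] / 2.0
        root = _TreeNode(children=[(nodes[a], half), (nodes[b], half)])
        return PhyloTree(root=root)

    while len(active) > 3:
        r = len(active)
        totals = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * D[(a, b)] - totals[a] - totals[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best  # type: ignore[misc]
        dab = D[(a, b)]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        # clamp negatives, moving the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_label = min(a, b)  # representative for tie-breaking
        parent = _TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        updates = {
            c: 0.5 * (D[(a, c)] + D[(b, c)] - dab)
            for c in active
            if c not in (a, b)
        }
        for c, d in updates.items():
            D[(new_label, c)] = D[(c, new_label)] = d
        active = sorted(set(active) - {a, b} | {new_label})
        nodes[new_label] = parent

    # final three clusters joined at the (trifurcating) root
    a, b, c = active
    la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    branches = [max(x, 0.0) for x in (la, lb, lc)]
    root = _TreeNode(children=list(zip((nodes[a], nodes[b], nodes[c]), branches)))
    return PhyloTree(root=root)
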