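"""Pan/core-genome statistics over an orthogroup presence matrix.

Presence throughout means copy number >= 1.  All statistics operate on the
orthogroup x genome copy-number matrix and are purely combinatorial:

* accumulation curves — mean pan- and core-genome size as genomes are added
  in random (or exhaustively enumerated) orders;
* occupancy spectrum — number of orthogroups present in exactly j genomes
  (singletons at j=1, the core at j=G);
* Venn partitions — for 2..6 genomes, the count of orthogroups in each
  region of the Venn diagram;
* differential query — orthogroups conserved in every genome of an include
  set and absent from every genome of an exclude set.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .orthology import PresenceMatrix

__all__ = [
    "AccumulationCurves",
    "OccupancySpectrum",
    "accumulation_curves",
    "occupancy_spectrum",
    "venn_partitions",
    "differential_query",
]


@dataclass
class AccumulationCurves:
    k: np.ndarray  # genome counts 1..G
    pan_mean: np.ndarray
    core_mean: np.ndarray
    n_orders: int
    seed: int | None  # None when all orderings were enumerated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "pan_mean": self.pan_mean, "core_mean": self.core_mean}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class OccupancySpectrum:
    counts: dict[int, int]  # j in 1..G -> number of orthogroups in exactly j genomes
    n_genomes: int

    @property
    def n_singletons(self) -> int:
        return self.counts.get(1, 0)

    @property
    def core_size(self) -> int:
        return self.counts.get(self.n_genomes, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_genomes": list(self.counts), "n_orthogroups": list(self.counts.values())}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _presence_bool(matrix: PresenceMatrix) -> np.ndarray:
    return (matrix.df.to_numpy() >= 1)


def accumulation_curves(
    matrix: PresenceMatrix,
    n_orders: int = 100,
    seed: int = 42,
    all_orders: bool = False,
) -> AccumulationCurves:
    """Pan- and core-genome accumulation curves.

    For each genome ordering, pan(k) is the number of orthogroups present in
    at least one of the first k genomes and core(k) the number present in all
    of them; means over orderings are reported per k.  ``all_orders=True``
    enumerates every permutation (feasible for small G) instead of sampling
    ``n_orders`` seeded random orderings.
    """
    pres = _presence_bool(matrix)
    n_og, G = pres.shape
    if G < 1:
        raise ValueError("need at least one genome")
    if all_orders:
        orderings: Iterable[Sequence[int]] = itertools.permutations(range(G))
    else:
        if n_orders < 1:
            raise ValueError(f"n_orders must be >= 1, got {n_orders}")
        rng = np.random.default_rng(seed)
        orderings = [rng.permutation(G) for _ in range(n_orders)]

    pan_sum = np.zeros(G)
    core_sum = np.zeros(G)
    count = 0
    for order in orderings:
        sub = pres[:, list(order)]
        any_cum = np.logical_or.accumulate(sub, axis=1)
        all_cum = np.logical_and.accumulate(sub, axis=1)
        pan_sum += any_cum.sum(axis=0)
        core_sum += all_cum.sum(axis=0)
        count += 1
    return AccumulationCurves(
        k=np.arange(1, G + 1),
        pan_mean=pan_sum / count,
        core_mean=core_sum / count,
        n_orders=count,
        seed=None if all_orders else seed,
    )


def occupancy_spectrum(matrix: PresenceMatrix) -> OccupancySpectrum:
    """Orthogroup occupancy histogram: counts[j] = orthogroups in exactly j genomes."""
    pres = _presence_bool(matrix)
    if pres.size == 0:
        raise ValueError("empty presence matrix")
    G = pres.shape[1]
    occ = pres.sum(axis=1)
    counts = {j: int((occ == j).sum()) for j in range(1, G + 1)}
    return OccupancySpectrum(counts=counts, n_genomes=G)


def venn_partitions(
    matrix: PresenceMatrix, genome_subset: Sequence[str]
) -> dict[frozenset[str], int]:
    """Venn-diagram region counts for 2..6 genomes.

    Each orthogroup present in at least one subset genome falls in exactly
    one region: the exact set of subset genomes containing it.  The returned
    map is keyed by that set (regions with zero orthogroups included, so the
    keys enumerate every non-empty subset signature).
    """
    subset = list(genome_subset)
    if not 2 <= len(subset) <= 6:
        raise ValueError(f"Venn subsets must have 2-6 genomes, got {len(subset)}")
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate genomes in Venn subset")
    pres = matrix.presence()[subset]
    regions: dict[frozenset[str], int] = {
        frozenset(c): 0
        for r in range(1, len(subset) + 1)
        for c in itertools.combinations(subset, r)
    }
    for _, row in pres.iterrows():
        sig = frozenset(g for g in subset if row[g])
        if sig:
            regions[sig] += 1
    return regions


def venn_to_json(regions: dict[frozenset[str], int], path: str | Path | None = None) -> str:
    payload = {"&".join(sorted(sig)): n for sig, n in sorted(
        regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    )}
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def differential_query(
    matrix: PresenceMatrix,
    include: Iterable[str],
    exclude: Iterable[str] = (),
) -> list[str]:
    """Orthogroups present in every ``include`` genome and absent from every
    ``exclude`` genome, sorted by og_id.  A genome named in both sets makes
    the result empty (presence and absence cannot both hold)."""
    include = list(include)
    exclude = list(exclude)
    if not include:
        raise ValueError("include set must be non-empty")
    if set(include) & set(exclude):
        return []
    pres = matrix.presence()
    for g in (*include, *exclude):
        if g not in pres.columns:
            raise ValueError(f"unknown genome {g!r}")
    mask = pres[include].all(axis=1)
    if exclude:
        mask &= ~pres[exclude].any(axis=1)
    return sorted(pres.index[mask])
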