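"""Independent oracles used by the test suite.

Everything here is deliberately written as straight-line brute force,
independent of the package's implementation paths: a codon-table translator,
an affine-gap dynamic-programming aligner, a string-rewriting evaluator for
module definitions, and exhaustive enumerations for the pan-genome
statistics.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np

# --- codon-by-codon bacterial (table 11) translator ----------------------------

_TABLE11 = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    _TABLE11[_b1 + _b2 + _b3] = _AA[_i]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate11(nuc: str) -> str:
    """Codon-by-codon translation, trailing stop stripped."""
    nuc = nuc.upper()
    protein = "".join(
        _TABLE11.get(nuc[i : i + 3], "X") for i in range(0, len(nuc) - len(nuc) % 3, 3)
    )
    return protein.rstrip("*")


# --- exhaustive affine-gap global alignment -------------------------------------

def nw_identity(a: str, b: str, matrix, gap_open: float = 11.0,
                gap_extend: float = 1.0) -> float:
    """Percent identity from an affine-gap Needleman-Wunsch alignment.

    Gotoh three-state DP with full traceback; identity counted over columns
    where neither side is a gap.
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    # traceback from the best final state
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][n, m])
    i, j = n, m
    ident = cols = 0
    while i > 0 or j > 0:
        if state == "M":
            cols += 1
            if a[i - 1] == b[j - 1]:
                ident += 1
            prev = max(
                ("M", "X", "Y"),
                key=lambda st: {"M": M, "X": X, "Y": Y}[st][i - 1, j - 1],
            )
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            state = "M" if M[i - 1, j] - gap_open >= X[i - 1, j] - gap_extend else "X"
            i -= 1
        else:
            state = "M" if M[i, j - 1] - gap_open >= Y[i, j - 1] - gap_extend else "Y"
            j -= 1
    return 100.0 * ident / cols if cols else 0.0


# --- string-rewriting evaluator for module definitions ---------------------------
# Splits the raw definition text at top-level separators (tracking parenthesis
# depth) instead of building a tree, so it shares no code with the parser.

def _split_top(text: str, seps: set[str]) -> list[str]:
    parts, depth, cur = [], 0, []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth == 0 and ch in seps and not (
            ch == "-" and text[i : i + 2] == "--" and _standalone_gap(text, i)
        ):
            parts.append("".join(cur))
            cur = []
            if ch == "-":
                cur.append("-")  # keep the optional marker with the member
            i += 1
            continue
        cur.append(ch)
        i += 1
    parts.append("".join(cur))
    return parts


def _standalone_gap(text: str, i: int) -> bool:
    before_ok = i == 0 or text[i - 1] in " (,"
    after_ok = i + 2 >= len(text) or text[i + 2] in " ),"
    return before_ok and after_ok


def eval_definition(text: str, kos: set[str], gap_satisfied: bool = True) -> float:
    """Evaluate a module definition string directly (oracle path)."""
    text = text.strip()
    steps = [s for s in _split_top(text, {" "}) if s.strip()]
    if len(steps) > 1:
        return sum(eval_definition(s, kos, gap_satisfied) for s in steps) / len(steps)
    text = steps[0].strip()

    alts = _split_top(text, {","})
    if len(alts) > 1:
        return max(eval_definition(a, kos, gap_satisfied) for a in alts)

    members = _split_top(text, {"+", "-"})
    if len(members) > 1:
        for m in members:
            m = m.strip()
            if m.startswith("-"):
                continue  # optional subunit
            if eval_definition(m, kos, gap_satisfied) < 1.0:
                return 0.0
        return 1.0
    text = members[0].strip()
    if text.startswith("-") and text != "--":
        text = text[1:]

    if text.startswith("(") and text.endswith(")"):
        return eval_definition(text[1:-1], kos, gap_satisfied)
    if text == "--":
        return 1.0 if gap_satisfied else 0.0
    return 1.0 if text in kos else 0.0


def definition_atoms(text: str) -> set[str]:
    import re

    return set(re.findall(r"K\d{5}", text))


# --- pan-genome brute force -------------------------------------------------------

def brute_accumulation(presence: np.ndarray, orderings: Iterable[Sequence[int]]):
    """Mean pan/core curves by naive set arithmetic over explicit orderings."""
    n_og, G = presence.shape
    groups = [set(np.flatnonzero(presence[i])) for i in range(n_og)]
    pan = np.zeros(G)
    core = np.zeros(G)
    count = 0
    for order in orderings:
        for k in range(1, G + 1):
            first = set(order[:k])
            pan[k - 1] += sum(1 for s in groups if s & first)
            core[k - 1] += sum(1 for s in groups if first <= s)
        count += 1
    return pan / count, core / count


def brute_venn(presence: np.ndarray, cols: Sequence[int]):
    """Signature -> count by per-row enumeration."""
    out: dict[frozenset[int], int] = {}
    for row in presence:
        sig = frozenset(c for c in cols if row[c])
        if sig:
            out[sig] = out.get(sig, 0) + 1
    return out


def brute_differential(presence: np.ndarray, og_ids: Sequence[str],
                       include: Sequence[int], exclude: Sequence[int]) -> list[str]:
    hits = []
    for i, row in enumerate(presence):
        if all(row[c] for c in include) and not any(row[c] for c in exclude):
            hits.append(og_ids[i])
    return sorted(hits)
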