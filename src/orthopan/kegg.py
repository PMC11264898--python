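"""KEGG module definition language: parser, completeness scoring and
orthogroup-based annotation propagation.

A KEGG module definition is a compact expression over KEGG ortholog (KO)
identifiers describing the enzymatic steps of a metabolic unit.  The
language, from tightest-binding operator to loosest:

* ``+`` joins the subunits of an enzymatic complex (all required); a
  leading ``-`` before a member marks it an optional subunit;
* ``,`` separates interchangeable alternatives (any one suffices);
* a space separates the sequential steps of the module (all contribute);
* parentheses group; ``--`` is a gap placeholder for a reaction with no
  known KO; ``M#####`` atoms reference other modules.

Completeness of a module in a genome is scored recursively from the set of
KOs present: an atom is 1 if its KO is present else 0; a gap counts as
satisfied; a complex is 1 iff every non-optional subunit is 1; an
alternation takes the maximum over its branches; a step sequence averages
its steps.  The root value is the module completeness, a fraction in
[0, 1] (1.0 = complete module).

Annotation propagation implements the orthogroup rule: a gene without a
direct KO assignment inherits a KO carried by another member of its
orthogroup, flagged ``propagated`` with the source orthogroup recorded.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orthology import OrthogroupSet

__all__ = [
    "ModuleDefinition",
    "ModuleParseError",
    "Atom",
    "StepSeq",
    "Alt",
    "Complex",
    "Optional",
    "Gap",
    "KoAssignment",
    "KoEntry",
    "CompletenessResult",
    "parse_module_definition",
    "module_completeness",
    "propagate_annotations",
    "completeness_matrix",
    "read_module_definitions",
    "read_ko_assignments",
]


class ModuleParseError(ValueError):
    """Malformed module definition; carries the 0-based failure position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


# --- expression tree ---------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    ko: str  # K##### or M#####

    def serialize(self) -> str:
        return self.ko


@dataclass(frozen=True)
class Gap:
    def serialize(self) -> str:
        return "--"


@dataclass(frozen=True)
class Optional:
    child: "Node"

    def serialize(self) -> str:  # only valid inside a Complex
        return self.child.serialize()


@dataclass(frozen=True)
class Complex:
    children: tuple["Node", ...]

    def serialize(self) -> str:
        parts = []
        for i, c in enumerate(self.children):
            inner = c.child if isinstance(c, Optional) else c
            s = inner.serialize()
            if not isinstance(inner, (Atom, Gap)):
                s = f"({s})"
            if isinstance(c, Optional):
                parts.append(f"-{s}")
            elif i > 0:
                parts.append(f"+{s}")
            else:
                parts.append(s)
        return "".join(parts)


@dataclass(frozen=True)
class Alt:
    children: tuple["Node", ...]

    def serialize(self) -> str:
        parts = []
        for c in self.children:
            s = c.serialize()
            if isinstance(c, (StepSeq, Alt)):
                s = f"({s})"
            parts.append(s)
        return ",".join(parts)


@dataclass(frozen=True)
class StepSeq:
    children: tuple["Node", ...]

    def serialize(self) -> str:
        parts = []
        for c in self.children:
            s = c.serialize()
            if isinstance(c, StepSeq):
                s = f"({s})"
            parts.append(s)
        return " ".join(parts)


Node = Atom | Gap | Optional | Complex | Alt | StepSeq


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    expression: Node

    def serialize(self) -> str:
        return self.expression.serialize()

    def atoms(self) -> set[str]:
        out: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, Atom):
                out.add(node.ko)
            elif isinstance(node, (Complex, Alt, StepSeq)):
                for c in node.children:
                    walk(c)
            elif isinstance(node, Optional):
                walk(node.child)

        walk(self.expression)
        return out


# --- tokenizer / parser ------------------------------------------------------

_ATOM_RE = re.compile(r"[KM]\d{5}")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """-> list of (kind, value, position); kinds: ATOM GAP LP RP COMMA PLUS MINUS SPACE"""
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            j = i
            while j < n and text[j].isspace():
                j += 1
            tokens.append(("SPACE", " ", i))
            i = j
        elif text.startswith("--", i):
            tokens.append(("GAP", "--", i))
            i += 2
        elif ch == "(":
            tokens.append(("LP", ch, i))
            i += 1
        elif ch == ")":
            tokens.append(("RP", ch, i))
            i += 1
        elif ch == ",":
            tokens.append(("COMMA", ch, i))
            i += 1
        elif ch == "+":
            tokens.append(("PLUS", ch, i))
            i += 1
        elif ch == "-":
            tokens.append(("MINUS", ch, i))
            i += 1
        else:
            m = _ATOM_RE.match(text, i)
            if m:
                tokens.append(("ATOM", m.group(), i))
                i = m.end()
            else:
                raise ModuleParseError(f"illegal token {text[i:i+6]!r}", i)
    return tokens


class _Parser:
    """Recursive descent; binding from tightest: '+/-', ',', space."""

    def __init__(self, tokens: list[tuple[str, str, int]], length: int):
        self.tokens = tokens
        self.pos = 0
        self.length = length

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next_pos(self) -> int:
        tok = self.peek()
        return tok[2] if tok else self.length

    def take(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse_steps(self) -> Node:
        steps = [self.parse_alt()]
        while True:
            tok = self.peek()
            if tok is None or tok[0] != "SPACE":
                break
            self.take()
            nxt = self.peek()
            if nxt is None or nxt[0] == "RP":  # trailing whitespace
                break
            steps.append(self.parse_alt())
        return steps[0] if len(steps) == 1 else StepSeq(tuple(steps))

    def parse_alt(self) -> Node:
        branches = [self.parse_complex()]
        while True:
            tok = self.peek()
            if tok is None or tok[0] != "COMMA":
                break
            self.take()
            branches.append(self.parse_complex())
        return branches[0] if len(branches) == 1 else Alt(tuple(branches))

    def parse_complex(self) -> Node:
        members: list[Node] = [self.parse_primary()]
        saw_op = False
        while True:
            tok = self.peek()
            if tok is None or tok[0] not in ("PLUS", "MINUS"):
                break
            op = self.take()
            child = self.parse_primary()
            saw_op = True
            members.append(Optional(child) if op[0] == "MINUS" else child)
        return members[0] if not saw_op else Complex(tuple(members))

    def parse_primary(self) -> Node:
        tok = self.peek()
        if tok is None:
            raise ModuleParseError("dangling operator or empty expression", self.length)
        kind, value, pos = tok
        if kind == "ATOM":
            self.take()
            return Atom(value)
        if kind == "GAP":
            self.take()
            return Gap()
        if kind == "LP":
            self.take()
            inner = self.parse_steps()
            closing = self.peek()
            if closing is None or closing[0] != "RP":
                raise ModuleParseError("unbalanced parentheses", self.next_pos())
            self.take()
            return inner
        raise ModuleParseError(f"unexpected {value!r}", pos)


def parse_module_definition(text: str, module_id: str = "") -> ModuleDefinition:
    """Parse one module definition string into its expression tree.

    Raises :class:`ModuleParseError` with the 0-based failure position for
    unbalanced parentheses, dangling operators or illegal tokens.
    """
    stripped = text.strip()
    if not stripped:
        raise ModuleParseError("empty definition", 0)
    tokens = _tokenize(text)
    # strip leading/trailing whitespace tokens
    while tokens and tokens[0][0] == "SPACE":
        tokens.pop(0)
    while tokens and tokens[-1][0] == "SPACE":
        tokens.pop()
    parser = _Parser(tokens, len(text))
    expr = parser.parse_steps()
    leftover = parser.peek()
    if leftover is not None:
        raise ModuleParseError(f"unexpected {leftover[1]!r}", leftover[2])
    return ModuleDefinition(module_id=module_id, expression=expr)


# --- completeness ------------------------------------------------------------

@dataclass
class CompletenessResult:
    module_id: str
    genome_id: str
    completeness: float  # fraction in [0, 1]
    satisfied_atoms: set[str]
    used_propagated: bool = False


def _evaluate(
    node: Node,
    ko_present: frozenset[str],
    nested: Mapping[str, ModuleDefinition],
    gap_satisfied: bool,
    _stack: frozenset[str] = frozenset(),
) -> float:
    if isinstance(node, Atom):
        ko = node.ko
        if ko.startswith("M"):
            if ko in nested:
                if ko in _stack:  # cyclic module reference: treat as unsatisfied
                    return 0.0
                return _evaluate(
                    nested[ko].expression, ko_present, nested, gap_satisfied,
                    _stack | {ko},
                )
            warnings.warn(
                f"module reference {ko} has no supplied definition; treated as unsatisfied",
                stacklevel=2,
            )
            return 0.0
        return 1.0 if ko in ko_present else 0.0
    if isinstance(node, Gap):
        return 1.0 if gap_satisfied else 0.0
    if isinstance(node, Complex):
        for child in node.children:
            if isinstance(child, Optional):
                continue
            if _evaluate(child, ko_present, nested, gap_satisfied, _stack) < 1.0:
                return 0.0
        return 1.0
    if isinstance(node, Alt):
        return max(
            _evaluate(c, ko_present, nested, gap_satisfied, _stack)
            for c in node.children
        )
    if isinstance(node, StepSeq):
        vals = [
            _evaluate(c, ko_present, nested, gap_satisfied, _stack)
            for c in node.children
        ]
        return sum(vals) / len(vals)
    if isinstance(node, Optional):  # only reachable if evaluated directly
        return _evaluate(node.child, ko_present, nested, gap_satisfied, _stack)
    raise TypeError(f"unknown node {node!r}")


def module_completeness(
    definition: ModuleDefinition,
    ko_present: Iterable[str],
    genome_id: str = "",
    nested: Mapping[str, ModuleDefinition] | None = None,
    gap_satisfied: bool = True,
) -> CompletenessResult:
    """Score a module definition against the KOs present in a genome.

    ``gap_satisfied`` controls whether ``--`` placeholders count as satisfied
    (default: yes, they denote reactions with no KO assigned).  ``nested``
    supplies definitions for M-number references; unresolved references are
    unsatisfied (with a warning).
    """
    kos = frozenset(ko_present)
    value = _evaluate(
        definition.expression, kos, nested or {}, gap_satisfied
    )
    return CompletenessResult(
        module_id=definition.module_id,
        genome_id=genome_id,
        completeness=value,
        satisfied_atoms=definition.atoms() & kos,
    )


# --- KO assignments and propagation ------------------------------------------

@dataclass(frozen=True)
class KoEntry:
    genome_id: str
    locus_tag: str
    ko: str
    provenance: str = "direct"  # direct | propagated
    source_orthogroup: str | None = None

    def __post_init__(self) -> None:
        if self.provenance == "propagated" and self.source_orthogroup is None:
            raise ValueError("propagated entries must cite a source orthogroup")


@dataclass
class KoAssignment:
    entries: list[KoEntry] = field(default_factory=list)

    def direct(self) -> list[KoEntry]:
        return [e for e in self.entries if e.provenance == "direct"]

    def kos_of_genome(self, genome_id: str, include_propagated: bool = True) -> set[str]:
        return {
            e.ko
            for e in self.entries
            if e.genome_id == genome_id
            and (include_propagated or e.provenance == "direct")
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.genome_id, e.locus_tag, e.ko, e.provenance, e.source_orthogroup or "")
                for e in self.entries
            ],
            columns=["genome_id", "locus_tag", "ko", "provenance", "source_orthogroup"],
        )


def propagate_annotations(
    assignments: KoAssignment,
    ogset: OrthogroupSet,
    genomes: Sequence | None = None,
) -> KoAssignment:
    """Spread direct KO annotations within orthogroups.

    For every KO carried directly by at least one member of an orthogroup,
    every other member lacking that direct annotation gains a ``propagated``
    entry citing the orthogroup.  Direct entries are untouched; the operation
    is idempotent (propagation only ever reads direct entries).
    """
    if genomes is not None:
        known = {
            (g.genome_id, f.locus_tag) for g in genomes for f in g.features
        }
        for e in assignments.entries:
            if (e.genome_id, e.locus_tag) not in known:
                raise ValueError(
                    f"KO assignment references unknown gene {e.locus_tag!r} "
                    f"in genome {e.genome_id!r}"
                )

    direct = assignments.direct()
    direct_keys = {(e.genome_id, e.locus_tag, e.ko) for e in direct}
    out = list(direct)

    for og_id in sorted(ogset.groups):
        members = ogset.groups[og_id]
        member_set = set(members)
        og_kos = sorted(
            {e.ko for e in direct if (e.genome_id, e.locus_tag) in member_set}
        )
        for ko in og_kos:
            for gid, tag in sorted(members):
                if (gid, tag, ko) in direct_keys:
                    continue
                out.append(
                    KoEntry(
                        genome_id=gid,
                        locus_tag=tag,
                        ko=ko,
                        provenance="propagated",
                        source_orthogroup=og_id,
                    )
                )
    return KoAssignment(entries=out)


# --- per-genome matrix -------------------------------------------------------

@dataclass
class CompletenessMatrix:
    results: dict[tuple[str, str], CompletenessResult]  # (module_id, genome_id)
    ko_gene_counts: dict[tuple[str, str], dict[str, int]]  # per cell: ko -> n genes
    use_propagated: bool

    def to_frame(self) -> pd.DataFrame:
        modules = sorted({m for m, _ in self.results})
        genomes = sorted({g for _, g in self.results})
        df = pd.DataFrame(index=modules, columns=genomes, dtype=float)
        for (m, g), res in self.results.items():
            df.loc[m, g] = res.completeness
        return df

    def to_json(self) -> str:
        import json

        payload = {
            f"{m}\t{g}": {
                "completeness": res.completeness,
                "satisfied_atoms": sorted(res.satisfied_atoms),
                "used_propagated": res.used_propagated,
                "ko_gene_counts": self.ko_gene_counts[(m, g)],
            }
            for (m, g), res in sorted(self.results.items())
        }
        return json.dumps(payload, indent=2)


def completeness_matrix(
    definitions: Sequence[ModuleDefinition],
    assignments: KoAssignment,
    genomes: Sequence[str],
    use_propagated: bool = False,
    gap_satisfied: bool = True,
) -> CompletenessMatrix:
    """Module x genome completeness with per-KO gene counts.

    Per genome, the KO set is the union over that genome's genes of their
    direct annotations, plus propagated ones when ``use_propagated`` is set.
    Each cell also records, per KO of the module, how many genes of the
    genome carry it (the counts displayed inside heatmap squares).
    """
    nested = {d.module_id: d for d in definitions if d.module_id}
    results: dict[tuple[str, str], CompletenessResult] = {}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for gid in genomes:
        entries = [
            e
            for e in assignments.entries
            if e.genome_id == gid
            and (use_propagated or e.provenance == "direct")
        ]
        ko_present = {e.ko for e in entries}
        direct_only = {e.ko for e in entries if e.provenance == "direct"}
        genes_per_ko: dict[str, set[str]] = {}
        for e in entries:
            genes_per_ko.setdefault(e.ko, set()).add(e.locus_tag)
        for d in definitions:
            res = module_completeness(
                d, ko_present, genome_id=gid, nested=nested,
                gap_satisfied=gap_satisfied,
            )
            res.used_propagated = bool(res.satisfied_atoms - direct_only)
            results[(d.module_id, gid)] = res
            counts[(d.module_id, gid)] = {
                ko: len(genes_per_ko.get(ko, ()))
                for ko in sorted(d.atoms())
                if not ko.startswith("M")
            }
    return CompletenessMatrix(
        results=results, ko_gene_counts=counts, use_propagated=use_propagated
    )


# --- plain-text I/O ----------------------------------------------------------

def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Two-column TSV (module_id, definition string) -> parsed definitions."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        module_id, _, text = line.partition("\t")
        out.append(parse_module_definition(text, module_id=module_id.strip()))
    return out


def read_ko_assignments(path: str | Path) -> KoAssignment:
    """TSV (genome_id, locus_tag, KO) -> direct KO assignments."""
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gid, tag, ko = line.rstrip("\n").split("\t")[:3]
        entries.append(KoEntry(genome_id=gid, locus_tag=tag, ko=ko))
    return KoAssignment(entries=entries)
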