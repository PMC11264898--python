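"""Search-bar query language over genes, products, genomes and annotations.

Queries combine terms with boolean operators and wildcards, e.g.::

    trp* AND NOT pseudo
    product:"ATP synthase" OR ko:K00001

Grammar: terms are bare words or quoted phrases, optionally prefixed with a
field name (``locus_tag``, ``gene_name``, ``product``, ``genome``, or an
annotation kind like ``ko``/``cog``/``pfam``); operators bind NOT > AND > OR
with parentheses for grouping; adjacency is an implicit AND; keywords are
case-insensitive.  ``*`` is the only wildcard (any run of characters).  Bare
terms match as substrings of any searchable field; field-prefixed terms
match whole tokens of that field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ingest import GenomeRecord

__all__ = [
    "Term",
    "And",
    "Or",
    "Not",
    "QueryParseError",
    "SearchIndex",
    "IndexEntry",
    "parse_query",
    "execute_query",
    "build_index",
]


class QueryParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class Term:
    pattern: str
    field: str | None = None  # None = any searchable field

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty search pattern")


@dataclass(frozen=True)
class And:
    left: "QueryNode"
    right: "QueryNode"


@dataclass(frozen=True)
class Or:
    left: "QueryNode"
    right: "QueryNode"


@dataclass(frozen=True)
class Not:
    child: "QueryNode"


QueryNode = Term | And | Or | Not


# --- parsing -------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lp>\() | (?P<rp>\)) |
        (?P<quoted>(?:[A-Za-z_][\w.]*:)?"[^"]*") |
        (?P<word>[^\s()"]+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            raise QueryParseError(f"cannot tokenize {text[pos:pos+10]!r}", pos)
        start = m.start(m.lastgroup)  # type: ignore[arg-type]
        if m.lastgroup == "lp":
            tokens.append(("LP", "(", start))
        elif m.lastgroup == "rp":
            tokens.append(("RP", ")", start))
        elif m.lastgroup == "quoted":
            tokens.append(("TERM", m.group("quoted"), start))
        else:
            word = m.group("word")
            upper = word.upper()
            if upper in ("AND", "OR", "NOT"):
                tokens.append((upper, word, start))
            else:
                if word.count('"') % 2:
                    raise QueryParseError("unbalanced quote", start)
                tokens.append(("TERM", word, start))
        pos = m.end()
    return tokens


def _make_term(raw: str, pos: int) -> Term:
    field_name: str | None = None
    body = raw
    m = re.match(r"([A-Za-z_][\w.]*):(.+)$", raw, re.DOTALL)
    if m:
        field_name, body = m.group(1).lower(), m.group(2)
    if body.startswith('"') and body.endswith('"') and len(body) >= 2:
        body = body[1:-1]
    if not body:
        raise QueryParseError("empty search term", pos)
    return Term(pattern=body, field=field_name)


class _QueryParser:
    def __init__(self, tokens: list[tuple[str, str, int]], length: int):
        self.tokens = tokens
        self.i = 0
        self.length = length

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse_or(self) -> QueryNode:
        node = self.parse_and()
        while (tok := self.peek()) and tok[0] == "OR":
            self.take()
            node = Or(node, self.parse_and())
        return node

    def parse_and(self) -> QueryNode:
        node = self.parse_unary()
        while (tok := self.peek()) is not None:
            if tok[0] == "AND":
                self.take()
                node = And(node, self.parse_unary())
            elif tok[0] in ("TERM", "NOT", "LP"):  # adjacency = implicit AND
                node = And(node, self.parse_unary())
            else:
                break
        return node

    def parse_unary(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("dangling operator", self.length)
        if tok[0] == "NOT":
            self.take()
            return Not(self.parse_unary())
        return self.parse_primary()

    def parse_primary(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("dangling operator", self.length)
        kind, value, pos = tok
        if kind == "LP":
            self.take()
            inner = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != "RP":
                p = closing[2] if closing else self.length
                raise QueryParseError("unbalanced parentheses", p)
            self.take()
            return inner
        if kind == "TERM":
            self.take()
            return _make_term(value, pos)
        raise QueryParseError(f"unexpected {value!r}", pos)


def parse_query(text: str) -> QueryNode:
    """Parse a search expression into a query AST."""
    if not text.strip():
        raise QueryParseError("empty query", 0)
    if text.count('"') % 2:
        raise QueryParseError("unbalanced quote", text.rfind('"'))
    parser = _QueryParser(_tokenize(text), len(text))
    node = parser.parse_or()
    leftover = parser.peek()
    if leftover is not None:
        raise QueryParseError(f"unexpected {leftover[1]!r}", leftover[2])
    return node


# --- index and execution --------------------------------------------------------

@dataclass(frozen=True)
class IndexEntry:
    genome_id: str
    locus_tag: str
    fields: Mapping[str, str]  # case-folded searchable fields


@dataclass
class SearchIndex:
    entries: list[IndexEntry] = field(default_factory=list)


def build_index(
    genomes: Iterable[GenomeRecord],
    annotations: Mapping[str, Iterable[tuple[str, str, str]]] | None = None,
) -> SearchIndex:
    """Index every gene feature.

    ``annotations`` maps an annotation kind (e.g. ``"ko"``, ``"cog"``,
    ``"pfam"``) to (genome_id, locus_tag, annotation_id) triples; the ids
    become searchable under that field name and under the generic
    ``annotations`` field.
    """
    ann: dict[tuple[str, str], dict[str, list[str]]] = {}
    if annotations:
        for kind, triples in annotations.items():
            for gid, tag, aid in triples:
                ann.setdefault((gid, tag), {}).setdefault(kind.lower(), []).append(aid)

    entries = []
    for g in genomes:
        for f in g.features:
            fields = {
                "locus_tag": f.locus_tag.casefold(),
                "gene_name": (f.gene_name or "").casefold(),
                "product": (f.product or "").casefold(),
                "genome": f"{g.genome_id} {g.display_name}".casefold(),
                "kind": f.feature_kind.casefold(),
            }
            extra = ann.get((g.genome_id, f.locus_tag), {})
            all_ids = []
            for kind, ids in extra.items():
                fields[kind] = " ".join(ids).casefold()
                all_ids.extend(ids)
            fields["annotations"] = " ".join(all_ids).casefold()
            entries.append(
                IndexEntry(genome_id=g.genome_id, locus_tag=f.locus_tag, fields=fields)
            )
    return SearchIndex(entries=entries)


def _pattern_regex(pattern: str, whole_token: bool) -> re.Pattern:
    body = ".*".join(re.escape(part) for part in pattern.casefold().split("*"))
    if whole_token:
        return re.compile(rf"(?:^|\s)(?:{body})(?:\s|$)")
    return re.compile(body)


def _matches(term: Term, entry: IndexEntry) -> bool:
    if term.field is not None:
        value = entry.fields.get(term.field)
        if value is None:
            return False
        return bool(_pattern_regex(term.pattern, whole_token=True).search(value))
    rx = _pattern_regex(term.pattern, whole_token=False)
    return any(rx.search(v) for v in entry.fields.values())


def execute_query(ast: QueryNode, index: SearchIndex) -> list[IndexEntry]:
    """Evaluate a query AST over the index; hits sorted by (genome, locus)."""
    universe = range(len(index.entries))

    def ev(node: QueryNode) -> set[int]:
        if isinstance(node, Term):
            return {i for i in universe if _matches(node, index.entries[i])}
        if isinstance(node, And):
            return ev(node.left) & ev(node.right)
        if isinstance(node, Or):
            return ev(node.left) | ev(node.right)
        if isinstance(node, Not):
            return set(universe) - ev(node.child)
        raise TypeError(f"unknown query node {node!r}")

    hits = [index.entries[i] for i in ev(ast)]
    hits.sort(key=lambda e: (e.genome_id, e.locus_tag))
    return hits


def search(text: str, index: SearchIndex) -> list[IndexEntry]:
    """Convenience: parse then execute."""
    return execute_query(parse_query(text), index)


def hits_to_tsv(hits: Sequence[IndexEntry]) -> str:
    """Serialize hits as a TSV table (genome_id, locus_tag, product)."""
    lines = ["genome_id\tlocus_tag\tproduct"]
    for h in hits:
        lines.append(f"{h.genome_id}\t{h.locus_tag}\t{h.fields.get('product', '')}")
    return "\n".join(lines) + "\n"
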