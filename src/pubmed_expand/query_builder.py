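"""Boolean query construction for PubMed.

Builds the five query forms emitted for a mapped term — the two
automatic-term-mapping shapes (q1 for a preferred-term match, q2 for an
entry-term or UMLS-synonym match), the entry-term title/abstract
expansion (q3), the UMLS-synonym expansion (q4) and their difference
(q5 = q4 NOT q3) — and renders them to exact PubMed query strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .terminology import MeshDescriptor, TerminologyIndex, normalize_spelling, umls_synonyms

__all__ = [
    "FIELD_TAGS",
    "Clause",
    "And",
    "Or",
    "Not",
    "Node",
    "BooleanQuery",
    "MatchResult",
    "tokenize",
    "map_term",
    "build_atm_query",
    "build_q3",
    "build_q4",
    "build_q5",
    "build_all",
    "render",
    "parse_query",
    "clause_set",
]

FIELD_TAGS = ("MeSH Terms", "All Fields", "TIAB", "SB")
_SB_PHRASES = ("MEDLINE", "OldMedline")


@dataclass(frozen=True)
class Clause:
    """A field-tagged phrase, e.g. ``"myocardial infarction"[MeSH Terms]``."""

    phrase: str
    field_tag: str

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("empty phrase")
        if '"' in self.phrase:
            raise ValueError(f"phrase contains a double quote (no escape syntax): {self.phrase!r}")
        if self.field_tag not in FIELD_TAGS:
            raise ValueError(f"unknown field tag {self.field_tag!r}")
        if self.field_tag == "SB" and self.phrase not in _SB_PHRASES:
            raise ValueError(f"[SB] clauses are restricted to {_SB_PHRASES}, got {self.phrase!r}")


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("empty AND group")


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("empty OR group")


@dataclass(frozen=True)
class Not:
    """Binary set difference: left NOT right."""

    left: "Node"
    right: "Node"


Node = Union[Clause, And, Or, Not]


@dataclass(frozen=True)
class BooleanQuery:
    root: Node
    label: str  # q1..q5

    def render(self) -> str:
        return render(self)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of mapping a free-text term against the terminology."""

    input_term: str
    descriptor_ui: Optional[str]
    matched_as: str  # preferred | entry | umls_synonym | none
    matched_term: Optional[str] = None

    def __post_init__(self) -> None:
        if self.matched_as == "none" and self.descriptor_ui is not None:
            raise ValueError("no-match results carry no descriptor ui")


def tokenize(term: str) -> list[str]:
    """Split a term on whitespace and commas into lowercased words."""
    if not term:
        raise ValueError("cannot tokenize an empty term")
    out = []
    for piece in term.replace(",", " ").split():
        out.append(piece.lower())
    return out


def map_term(index: TerminologyIndex, term: str) -> MatchResult:
    """Map a user term to a descriptor, preferring preferred-term matches.

    Normalized-exact comparison against preferred terms, then entry
    terms, then UMLS synonyms; the first hit (in descriptor order) wins.
    """
    norm = normalize_spelling(term)
    for d in index.descriptors.values():
        if normalize_spelling(d.preferred_term) == norm:
            return MatchResult(term, d.ui, "preferred", d.preferred_term)
    for d in index.descriptors.values():
        for entry in d.entry_terms:
            if normalize_spelling(entry) == norm:
                return MatchResult(term, d.ui, "entry", entry)
    for d in index.descriptors.values():
        for syn in umls_synonyms(index, d.ui, drop_nos=False):
            if normalize_spelling(syn) == norm:
                return MatchResult(term, d.ui, "umls_synonym", syn)
    return MatchResult(term, None, "none")


def _phrase(term: str) -> str:
    return normalize_spelling(term)


def _atm_clauses(term: str, include_mesh: bool) -> list[Node]:
    """The ATM expansion of one term: [MeSH Terms], token AND group, phrase.

    Single-word terms skip the degenerate one-token AND group.
    """
    phrase = _phrase(term)
    tokens = tokenize(term)
    nodes: list[Node] = []
    if include_mesh:
        nodes.append(Clause(phrase, "MeSH Terms"))
    if len(tokens) > 1:
        nodes.append(And(tuple(Clause(t, "All Fields") for t in tokens)))
    nodes.append(Clause(phrase, "All Fields"))
    return nodes


def build_atm_query(match: MatchResult, index: TerminologyIndex) -> BooleanQuery:
    """The query PubMed's term mapping would run for a matched term.

    A preferred-term match yields q1; an entry-term or UMLS-synonym match
    yields q2 (q1's clauses plus the matched term's own expansion).
    """
    if match.matched_as == "none" or match.descriptor_ui is None:
        raise ValueError(f"term {match.input_term!r} did not map to a descriptor")
    descriptor = index.descriptor(match.descriptor_ui)
    nodes = _atm_clauses(descriptor.preferred_term, include_mesh=True)
    if match.matched_as == "preferred":
        label = "q1"
    else:
        label = "q2"
        assert match.matched_term is not None
        nodes.extend(_atm_clauses(match.matched_term, include_mesh=False))
    root: Node = nodes[0] if len(nodes) == 1 else Or(tuple(nodes))
    return BooleanQuery(root, label)


def _tiab_block(phrases: Sequence[str]) -> Or:
    return Or(tuple(Clause(p, "TIAB") for p in phrases))


def _expansion_query(
    descriptor: MeshDescriptor, phrases: Sequence[str], excluded_subsets: Sequence[str], label: str
) -> BooleanQuery:
    sb: Node
    if len(excluded_subsets) == 1:
        sb = Clause(excluded_subsets[0], "SB")
    else:
        sb = Or(tuple(Clause(s, "SB") for s in excluded_subsets))
    root = Or(
        (
            Clause(_phrase(descriptor.preferred_term), "MeSH Terms"),
            Not(_tiab_block(phrases), sb),
        )
    )
    return BooleanQuery(root, label)


def build_q3(
    descriptor: MeshDescriptor, entry_terms: Optional[Sequence[str]] = None
) -> BooleanQuery:
    """Entry-term expansion: MeSH hits plus unindexed title/abstract hits.

    Shape: preferred[MeSH Terms] OR ((preferred and every entry term as
    [TIAB] phrases) NOT MEDLINE[SB]).  No token AND groups appear inside
    the [TIAB] block.
    """
    if entry_terms is None:
        entry_terms = descriptor.entry_terms
    phrases = [_phrase(descriptor.preferred_term)] + [_phrase(t) for t in entry_terms]
    return _expansion_query(descriptor, phrases, ["MEDLINE"], "q3")


def build_q4(
    descriptor: MeshDescriptor,
    entry_terms: Optional[Sequence[str]] = None,
    synonyms: Sequence[str] = (),
) -> BooleanQuery:
    """UMLS-synonym expansion: q3's [TIAB] block extended with each synonym.

    The subset exclusion widens to (MEDLINE[SB] OR OldMedline[SB]) —
    deliberately asymmetric with q3, which excludes MEDLINE[SB] only.
    ``synonyms`` must already be deduplicated (see terminology.umls_synonyms).
    """
    if entry_terms is None:
        entry_terms = descriptor.entry_terms
    phrases = (
        [_phrase(descriptor.preferred_term)]
        + [_phrase(t) for t in entry_terms]
        + [_phrase(s) for s in synonyms]
    )
    return _expansion_query(descriptor, phrases, ["MEDLINE", "OldMedline"], "q4")


def build_q5(q4: BooleanQuery, q3: BooleanQuery) -> BooleanQuery:
    """The difference query picking up synonym-only citations: q4 NOT q3."""
    if q4.label != "q4" or q3.label != "q3":
        raise ValueError(f"build_q5 expects (q4, q3), got ({q4.label}, {q3.label})")
    return BooleanQuery(Not(q4.root, q3.root), "q5")


def build_all(
    index: TerminologyIndex, term: str, drop_nos: bool = False
) -> dict[str, BooleanQuery]:
    """Every applicable query form for a user term, keyed by label.

    q1 is built on the descriptor's preferred term; q2 appears only when
    the term matched as an entry term or UMLS synonym.
    """
    match = map_term(index, term)
    if match.matched_as == "none" or match.descriptor_ui is None:
        raise ValueError(f"term {term!r} did not map to any descriptor")
    descriptor = index.descriptor(match.descriptor_ui)
    synonyms = umls_synonyms(index, match.descriptor_ui, drop_nos=drop_nos)

    queries: dict[str, BooleanQuery] = {}
    preferred_match = MatchResult(
        descriptor.preferred_term, descriptor.ui, "preferred", descriptor.preferred_term
    )
    queries["q1"] = build_atm_query(preferred_match, index)
    if match.matched_as != "preferred":
        queries["q2"] = build_atm_query(match, index)
    queries["q3"] = build_q3(descriptor)
    queries["q4"] = build_q4(descriptor, synonyms=synonyms)
    queries["q5"] = build_q5(queries["q4"], queries["q3"])
    return queries


# --- rendering ---------------------------------------------------------


def _render_node(node: Node, top: bool) -> str:
    if isinstance(node, Clause):
        if node.field_tag == "SB":
            return f"{node.phrase}[SB]"
        return f'"{node.phrase}"[{node.field_tag}]'
    if isinstance(node, And):
        body = " AND ".join(_render_node(c, top=False) for c in node.children)
    elif isinstance(node, Or):
        body = " OR ".join(_render_node(c, top=False) for c in node.children)
    elif isinstance(node, Not):
        body = f"{_render_node(node.left, top=False)} NOT {_render_node(node.right, top=False)}"
    else:  # pragma: no cover
        raise TypeError(f"not a query node: {node!r}")
    return body if top else f"({body})"


def render(query: Union[BooleanQuery, Node]) -> str:
    """Deterministic PubMed string for a query (byte-stable across calls)."""
    node = query.root if isinstance(query, BooleanQuery) else query
    return _render_node(node, top=True)


def clause_set(query: Union[BooleanQuery, Node]) -> frozenset[tuple[str, str]]:
    """All (phrase, field_tag) pairs in a query, for order-insensitive comparison."""
    node = query.root if isinstance(query, BooleanQuery) else query
    out: set[tuple[str, str]] = set()

    def walk(n: Node) -> None:
        if isinstance(n, Clause):
            out.add((n.phrase, n.field_tag))
        elif isinstance(n, (And, Or)):
            for c in n.children:
                walk(c)
        else:
            walk(n.left)
            walk(n.right)

    walk(node)
    return frozenset(out)


# --- parsing (inverse of render, for the local retrieval provider) -----


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def parse(self) -> Node:
        node = self._expr()
        self._ws()
        if self.pos != len(self.text):
            raise ValueError(f"trailing input at offset {self.pos}: {self.text[self.pos:]!r}")
        return node

    def _ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] == " ":
            self.pos += 1

    def _expr(self) -> Node:
        node = self._operand()
        while True:
            self._ws()
            op = self._peek_op()
            if op is None:
                return node
            operand = self._operand()
            if op == "NOT":
                node = Not(node, operand)
            elif op == "AND":
                if isinstance(node, And):
                    node = And(node.children + (operand,))
                else:
                    node = And((node, operand))
            else:
                if isinstance(node, Or):
                    node = Or(node.children + (operand,))
                else:
                    node = Or((node, operand))

    def _peek_op(self) -> Optional[str]:
        for op in ("AND", "OR", "NOT"):
            token = op + " "
            if self.text.startswith(token, self.pos):
                self.pos += len(token)
                return op
        return None

    def _operand(self) -> Node:
        self._ws()
        if self.pos >= len(self.text):
            raise ValueError("unexpected end of query")
        ch = self.text[self.pos]
        if ch == "(":
            self.pos += 1
            node = self._expr()
            self._ws()
            if self.pos >= len(self.text) or self.text[self.pos] != ")":
                raise ValueError(f"unbalanced parenthesis at offset {self.pos}")
            self.pos += 1
            return node
        if ch == '"':
            end = self.text.find('"', self.pos + 1)
            if end < 0:
                raise ValueError("unterminated phrase quote")
            phrase = self.text[self.pos + 1 : end]
            self.pos = end + 1
            return Clause(phrase, self._tag())
        # bare subset clause, e.g. MEDLINE[SB]
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in " []()":
            self.pos += 1
        word = self.text[start : self.pos]
        if not word:
            raise ValueError(f"cannot parse operand at offset {start}")
        tag = self._tag()
        if tag != "SB":
            raise ValueError(f"unquoted phrase {word!r} only allowed with [SB]")
        return Clause(word, tag)

    def _tag(self) -> str:
        if self.pos >= len(self.text) or self.text[self.pos] != "[":
            raise ValueError(f"expected field tag at offset {self.pos}")
        end = self.text.find("]", self.pos)
        if end < 0:
            raise ValueError("unterminated field tag")
        tag = self.text[self.pos + 1 : end]
        self.pos = end + 1
        if tag not in FIELD_TAGS:
            raise ValueError(f"unknown field tag {tag!r}")
        return tag


def parse_query(text: str, label: str = "parsed") -> BooleanQuery:
    """Parse a rendered query string back to an AST (render's inverse)."""
    return BooleanQuery(_Parser(text).parse(), label)
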