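"""Domain types for annotated sentences, parses, and relation instances.

The corpus container is a list of :class:`AnnotatedSentence`, each carrying a
pre-tokenized sentence, entity mentions as inclusive 1-based token spans, and
optionally a gold set of interacting mention pairs.  Dependency analyses are
attached from CoNLL-U files and constituency analyses from Penn-bracketed
trees; both parse layers are validated against the token sequence at load
time so downstream rules can rely on alignment.

The native sentence serialization is JSON-lines: one JSON object per line
with keys ``sid``, ``tokens``, ``entities`` and ``gold``.  This keeps the
corpus pre-tokenized and offset-free, so no tokenizer is needed anywhere in
the pipeline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

__all__ = [
    "Token",
    "EntityMention",
    "AnnotatedSentence",
    "DependencyGraph",
    "ConstituencyTree",
    "TreeNode",
    "EntityPairInstance",
    "CorpusError",
    "ParseError",
    "ValidationError",
    "AlignmentError",
    "read_sentences",
    "write_sentences",
    "attach_dependencies",
    "attach_constituents",
    "read_conllu",
    "read_bracketed_trees",
]


class CorpusError(Exception):
    """Base class for corpus loading/validation failures."""


class ParseError(CorpusError):
    """A file is syntactically malformed (names the offending line)."""


class ValidationError(CorpusError):
    """A record violates a domain invariant (spans, tree property, ...)."""


class AlignmentError(CorpusError):
    """A parse layer does not line up with the sentence tokens."""


_VERB_TAGS = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD"}
_NOUN_TAGS = {"NN", "NNS", "NNP", "NNPS"}


def coarse_pos(fine_tag: str) -> str:
    """Map a Penn-style fine tag to the coarse category verb/noun/other."""
    if fine_tag in _VERB_TAGS:
        return "verb"
    if fine_tag in _NOUN_TAGS:
        return "noun"
    return "other"


@dataclass(frozen=True)
class Token:
    """A single token with 1-based sentence position."""

    index: int
    surface: str
    lemma: str
    pos: str = "other"  # coarse category: verb | noun | other
    tag: str = ""       # fine POS tag string (may be empty)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"token index must be >= 1, got {self.index}")
        if not self.surface:
            raise ValidationError("token surface must be non-empty")

    @property
    def is_verb(self) -> bool:
        return self.pos == "verb"


@dataclass(frozen=True)
class EntityMention:
    """A named entity occupying an inclusive token span [start, end]."""

    id: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"entity {self.id}: span start {self.start} > end {self.end}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class DependencyGraph:
    """A dependency tree over token indices, plus an artificial root 0.

    Edges are (head, dependent, relation) triples.  Exactly one head per
    token is enforced (basic-dependency trees only); cycles are rejected.
    Path queries ignore edge direction.
    """

    ROOT = 0

    def __init__(self, n_tokens: int, edges: Iterable[tuple[int, int, str]]):
        self.n_tokens = n_tokens
        self.edges: list[tuple[int, int, str]] = []
        head_of: dict[int, int] = {}
        for head, dep, rel in edges:
            if not (0 <= head <= n_tokens):
                raise ValidationError(f"edge head {head} out of range 0..{n_tokens}")
            if not (1 <= dep <= n_tokens):
                raise ValidationError(f"edge dependent {dep} out of range 1..{n_tokens}")
            if dep in head_of:
                raise ValidationError(
                    f"token {dep} has multiple heads ({head_of[dep]} and {head}); "
                    "only basic dependency trees are accepted"
                )
            head_of[dep] = head
            self.edges.append((head, dep, rel))
        self._head_of = head_of
        self._check_acyclic()
        # undirected view over real tokens only (root excluded): rule
        # distances are measured between words, never through the root
        g = nx.Graph()
        g.add_nodes_from(range(1, n_tokens + 1))
        for head, dep, _ in self.edges:
            if head != self.ROOT:
                g.add_edge(head, dep)
        self._undirected = g

    def _check_acyclic(self) -> None:
        for start in self._head_of:
            seen = set()
            node = start
            while node in self._head_of:
                if node in seen:
                    raise ValidationError(f"cyclic heads involving token {start}")
                seen.add(node)
                node = self._head_of[node]

    @property
    def undirected(self) -> nx.Graph:
        return self._undirected

    def head(self, index: int) -> Optional[int]:
        return self._head_of.get(index)

    def relation(self, index: int) -> Optional[str]:
        for head, dep, rel in self.edges:
            if dep == index:
                return rel
        return None


@dataclass
class TreeNode:
    """A node of a constituency tree.

    Internal nodes carry a phrase label and >= 1 children; leaves carry the
    1-based token index they align to (set during attachment).
    """

    label: str
    children: list["TreeNode"] = field(default_factory=list)
    token_index: Optional[int] = None  # set on leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_span(self) -> tuple[int, int]:
        """Inclusive token-index span covered by this subtree."""
        lv = self.leaves()
        return (lv[0].token_index, lv[-1].token_index)  # type: ignore[return-value]

    def iter_nodes(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def dominates_span(self, start: int, end: int) -> bool:
        """True iff the full inclusive token span [start, end] is under this node."""
        lo, hi = self.leaf_span()
        return lo <= start and end <= hi


class ConstituencyTree:
    """A rooted ordered constituency tree whose leaves map 1:1 to tokens."""

    def __init__(self, root: TreeNode, n_tokens: int):
        leaves = root.leaves()
        if len(leaves) != n_tokens:
            raise AlignmentError(
                f"tree has {len(leaves)} leaves but sentence has {n_tokens} tokens"
            )
        for i, leaf in enumerate(leaves, start=1):
            leaf.token_index = i
        for node in root.iter_nodes():
            if not node.is_leaf and not node.children:
                raise ValidationError("internal node with no children")
        self.root = root
        self.n_tokens = n_tokens

    def minimal_dominating(self, start: int, end: int) -> TreeNode:
        """Lowest node whose leaf span contains [start, end]."""
        node = self.root
        while True:
            for child in node.children:
                if not child.is_leaf and child.dominates_span(start, end):
                    node = child
                    break
            else:
                return node


@dataclass(frozen=True)
class EntityPairInstance:
    """An unordered co-mention of two entities, ordered by surface position."""

    sid: str
    m1: EntityMention
    m2: EntityMention
    label: str = "unknown"  # positive | negative | unknown

    def __post_init__(self) -> None:
        if self.m1.end >= self.m2.start:
            raise ValidationError(
                f"pair ({self.m1.id},{self.m2.id}) in {self.sid}: "
                "first mention must precede second in surface order"
            )

    @property
    def key(self) -> tuple[str, frozenset]:
        return (self.sid, frozenset({self.m1.id, self.m2.id}))


@dataclass
class AnnotatedSentence:
    """A pre-tokenized sentence with entity mentions and optional gold pairs."""

    sid: str
    tokens: list[Token]
    entities: list[EntityMention]
    gold_pairs: set[frozenset] = field(default_factory=set)
    dependencies: Optional[DependencyGraph] = None
    constituents: Optional[ConstituencyTree] = None

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens, start=1):
            if tok.index != i:
                raise ValidationError(
                    f"{self.sid}: token indices must be consecutive from 1 "
                    f"(position {i} has index {tok.index})"
                )
        n = len(self.tokens)
        seen_spans: dict[tuple[int, int], str] = {}
        kept: list[EntityMention] = []
        for ent in self.entities:
            if ent.end > n:
                raise ValidationError(
                    f"{self.sid}: entity {ent.id} span {ent.span} exceeds {n} tokens"
                )
            if ent.span in seen_spans:
                continue  # identical spans deduplicated by first id
            for other_span in seen_spans:
                if ent.start <= other_span[1] and other_span[0] <= ent.end:
                    raise ValidationError(
                        f"{self.sid}: entity {ent.id} span {ent.span} overlaps "
                        f"{seen_spans[other_span]} span {other_span}"
                    )
            seen_spans[ent.span] = ent.id
            kept.append(ent)
        self.entities = kept
        ids = {e.id for e in self.entities}
        for pair in self.gold_pairs:
            if not pair <= ids:
                raise ValidationError(
                    f"{self.sid}: gold pair {set(pair)} references unknown mention ids"
                )

    def entity_by_id(self, eid: str) -> EntityMention:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(eid)

    def entity_pairs(self, include_self_name: bool = True) -> list[EntityPairInstance]:
        """All unordered mention pairs, ordered by surface position.

        With ``include_self_name=False``, pairs whose two mentions share a
        canonical name (self-pairs) are skipped.
        """
        ordered = sorted(self.entities, key=lambda e: e.start)
        pairs = []
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                a, b = ordered[i], ordered[j]
                if not include_self_name and a.name.lower() == b.name.lower():
                    continue
                pairs.append(EntityPairInstance(self.sid, a, b))
        return pairs

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


# ---------------------------------------------------------------------------
# Sentence JSON-lines format


def _sentence_from_record(rec: dict, lineno: int) -> AnnotatedSentence:
    try:
        tokens = []
        for i, t in enumerate(rec["tokens"], start=1):
            if isinstance(t, str):
                tokens.append(Token(i, t, t.lower()))
            else:
                tag = t.get("tag", "")
                tokens.append(
                    Token(
                        i,
                        t["surface"],
                        t.get("lemma", t["surface"].lower()),
                        t.get("pos", coarse_pos(tag)),
                        tag,
                    )
                )
        entities = [
            EntityMention(e["id"], int(e["start"]), int(e["end"]), e.get("name", e["id"]))
            for e in rec.get("entities", [])
        ]
        gold = {frozenset(p) for p in rec.get("gold", [])}
        return AnnotatedSentence(rec["sid"], tokens, entities, gold)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"line {lineno}: malformed sentence record ({exc})") from exc


def read_sentences(path) -> list[AnnotatedSentence]:
    """Read a JSON-lines sentence file; blank lines are skipped."""
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            sentences.append(_sentence_from_record(rec, lineno))
    return sentences


def write_sentences(sentences: Sequence[AnnotatedSentence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            rec = {
                "sid": s.sid,
                "tokens": [
                    {"surface": t.surface, "lemma": t.lemma, "pos": t.pos, "tag": t.tag}
                    for t in s.tokens
                ],
                "entities": [
                    {"id": e.id, "start": e.start, "end": e.end, "name": e.name}
                    for e in s.entities
                ],
                "gold": [sorted(p) for p in sorted(s.gold_pairs, key=sorted)],
            }
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# CoNLL-U ingestion (10-column, '#' comments, multiword/empty rows skipped)


def read_conllu(path) -> list[list[tuple[int, str, str, int, str]]]:
    """Parse a CoNLL-U file into per-sentence rows (id, form, lemma, head, deprel)."""
    sentences: list[list[tuple[int, str, str, int, str]]] = []
    rows: list[tuple[int, str, str, int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                if rows:
                    sentences.append(rows)
                    rows = []
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ParseError(f"line {lineno}: expected 10 tab-separated columns")
            tid = cols[0]
            if "-" in tid or "." in tid:
                continue  # multiword-token and empty-node rows carry no head
            try:
                rows.append((int(tid), cols[1], cols[2], int(cols[6]), cols[7]))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer ID or HEAD") from exc
    if rows:
        sentences.append(rows)
    return sentences


def attach_dependencies(sentences: Sequence[AnnotatedSentence], path) -> list[AnnotatedSentence]:
    """Attach validated dependency trees from a CoNLL-U file, in order."""
    parsed = read_conllu(path)
    if len(parsed) != len(sentences):
        raise AlignmentError(
            f"CoNLL-U has {len(parsed)} sentences, corpus has {len(sentences)}"
        )
    for sent, rows in zip(sentences, parsed):
        if len(rows) != len(sent.tokens):
            raise AlignmentError(
                f"{sent.sid}: CoNLL-U has {len(rows)} tokens, sentence has "
                f"{len(sent.tokens)}"
            )
        edges = [(head, tid, rel) for tid, _, _, head, rel in rows]
        sent.dependencies = DependencyGraph(len(sent.tokens), edges)
    return list(sentences)


# ---------------------------------------------------------------------------
# Penn-bracketed constituency trees (one tree per line)

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_bracketed(text: str) -> TreeNode:
    """Parse one Penn-style bracketed tree, e.g. ``(S (NP (NN A)) (VP ...))``."""
    items = _TOKEN_RE.findall(text)
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        if pos >= len(items) or items[pos] != "(":
            raise ParseError(f"expected '(' at item {pos} of bracketed tree")
        pos += 1
        if pos >= len(items) or items[pos] in "()":
            raise ParseError("missing node label in bracketed tree")
        node = TreeNode(items[pos])
        pos += 1
        while pos < len(items) and items[pos] != ")":
            if items[pos] == "(":
                node.children.append(parse_node())
            else:
                node.children.append(TreeNode(items[pos]))
                pos += 1
        if pos >= len(items):
            raise ParseError("unbalanced brackets: missing ')'")
        pos += 1
        if not node.children:
            raise ParseError(f"internal node {node.label!r} has no children")
        return node

    root = parse_node()
    if pos != len(items):
        raise ParseError("unbalanced brackets: trailing material after root")
    return root


def read_bracketed_trees(path) -> list[TreeNode]:
    trees = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_bracketed(line))
            except ParseError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return trees


def attach_constituents(sentences: Sequence[AnnotatedSentence], path) -> list[AnnotatedSentence]:
    """Attach constituency trees (one bracketed tree per line), in order."""
    trees = read_bracketed_trees(path)
    if len(trees) != len(sentences):
        raise AlignmentError(
            f"tree file has {len(trees)} trees, corpus has {len(sentences)}"
        )
    for sent, root in zip(sentences, trees):
        sent.constituents = ConstituencyTree(root, len(sent.tokens))
    return list(sentences)
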