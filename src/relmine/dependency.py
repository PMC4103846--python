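"""Dependency-distance computation and the RD1/RD2 extraction rules.

Dependency distance between two words is the number of links on the
shortest undirected path between them in the dependency tree; direction is
ignored.  RD1 proposes a relation for an entity pair whenever some
interaction word lies within a bounded dependency distance (default 4) of
both entities.  RD2 then drops candidates whose interaction word is a verb
that does not occur between the two mentions in surface order — interaction
verbs overwhelmingly sit between the entities they relate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .corpus import AnnotatedSentence, DependencyGraph, EntityMention, EntityPairInstance
from .lexicon import InteractionLexicon

__all__ = [
    "RelationCandidate",
    "dependency_distance",
    "shortest_dependency_path",
    "entity_anchor",
    "apply_rd1",
    "apply_rd2",
]

INF = math.inf


@dataclass(frozen=True)
class RelationCandidate:
    """An entity pair with rule evidence for an interaction."""

    pair: EntityPairInstance
    word_index: int          # token index of the interaction word
    word_lemma: str
    rule: str                # "RD" or "RP"
    dd1: float = INF         # dependency distance entity1 <-> word (RD only)
    dd2: float = INF
    evidence: tuple = ()     # RD: (path1, path2); RP: (parent_label, np_span, vp_span)

    @property
    def key(self) -> tuple[str, frozenset]:
        return self.pair.key


def dependency_distance(g: DependencyGraph, w1: int, w2: int) -> float:
    """Number of links on the shortest undirected path; inf if disconnected."""
    for w in (w1, w2):
        if not 1 <= w <= g.n_tokens:
            raise ValueError(f"token index {w} not in graph (1..{g.n_tokens})")
    if w1 == w2:
        return 0
    try:
        return float(nx.shortest_path_length(g.undirected, w1, w2))
    except nx.NetworkXNoPath:
        return INF


def shortest_dependency_path(g: DependencyGraph, w1: int, w2: int) -> Optional[list[int]]:
    """Token indices along the shortest undirected path, or None."""
    try:
        return list(nx.shortest_path(g.undirected, w1, w2))
    except nx.NetworkXNoPath:
        return None


def entity_anchor(mention: EntityMention) -> int:
    """Token used as the entity's dependency node: the last token of the span
    (English noun phrases tend to be head-final)."""
    return mention.end


def apply_rd1(
    sentence: AnnotatedSentence,
    lexicon: InteractionLexicon,
    max_dd: int = 4,
) -> list[RelationCandidate]:
    """RD1: both entities within dependency distance ``max_dd`` of the same
    interaction word.  Emits one candidate per (pair, word)."""
    g = sentence.dependencies
    if g is None:
        raise ValueError(f"{sentence.sid}: no dependency graph attached")
    word_indices = [
        t.index
        for t in sentence.tokens
        if lexicon.matches(t.lemma, t.surface)
        and not any(e.start <= t.index <= e.end for e in sentence.entities)
    ]
    out: list[RelationCandidate] = []
    for pair in sentence.entity_pairs():
        a1, a2 = entity_anchor(pair.m1), entity_anchor(pair.m2)
        for w in word_indices:
            d1 = dependency_distance(g, a1, w)
            if d1 > max_dd:
                continue
            d2 = dependency_distance(g, a2, w)
            if d2 > max_dd:
                continue
            token = sentence.tokens[w - 1]
            out.append(
                RelationCandidate(
                    pair=pair,
                    word_index=w,
                    word_lemma=token.lemma,
                    rule="RD",
                    dd1=d1,
                    dd2=d2,
                    evidence=(
                        tuple(shortest_dependency_path(g, a1, w) or ()),
                        tuple(shortest_dependency_path(g, a2, w) or ()),
                    ),
                )
            )
    return out


def apply_rd2(
    candidates: Sequence[RelationCandidate],
    sentence: AnnotatedSentence,
) -> list[RelationCandidate]:
    """RD2: a verb interaction word must occur strictly between the two
    mentions in surface order; noun interaction words pass unconditionally."""
    kept = []
    for cand in candidates:
        token = sentence.tokens[cand.word_index - 1]
        if token.is_verb:
            if not (cand.pair.m1.end < cand.word_index < cand.pair.m2.start):
                continue
        kept.append(cand)
    return kept
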