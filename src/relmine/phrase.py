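"""Constituency NP+VP rules RP1/RP2.

RP1 looks for a sibling NP/VP pair under a common parent where the NP
subtree dominates one entity's full span and the VP subtree the other's —
this captures partial clause structure up to the full sentence (when the
parent is the root).  RP2 then requires an interaction word among the VP
subtree's leaves.  These rules recover long-range relations whose
dependency paths are too long for the RD rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus import AnnotatedSentence, ConstituencyTree, EntityMention, EntityPairInstance, TreeNode
from .dependency import RelationCandidate
from .lexicon import InteractionLexicon

__all__ = ["NpVpStructure", "find_np_vp", "apply_rp2"]


@dataclass(frozen=True)
class NpVpStructure:
    """A sibling NP/VP pair dominating the two entities of a candidate pair."""

    parent: TreeNode
    np_node: TreeNode
    vp_node: TreeNode
    np_entity: EntityMention
    vp_entity: EntityMention
    np_direct: bool          # NP is the minimal node dominating its entity
    vp_direct: bool
    is_full_sentence: bool   # parent is the tree root


def _label_is(node: TreeNode, prefix: str) -> bool:
    return not node.is_leaf and (node.label == prefix or node.label.startswith(prefix + "-"))


def find_np_vp(
    tree: ConstituencyTree,
    e1: EntityMention,
    e2: EntityMention,
    require_np_before_vp: bool = True,
) -> list[NpVpStructure]:
    """All (parent, NP, VP) sibling structures covering the two entities.

    Either entity may fill the NP role; domination must cover the entity's
    full token span.  By default the NP sibling must precede the VP sibling,
    matching canonical S -> NP VP order.
    """
    if tree is None:
        raise ValueError("no constituency tree attached")
    out = []
    for parent in tree.root.iter_nodes():
        if parent.is_leaf:
            continue
        kids = parent.children
        for i, np_node in enumerate(kids):
            if not _label_is(np_node, "NP"):
                continue
            candidates_vp = kids[i + 1 :] if require_np_before_vp else kids
            for vp_node in candidates_vp:
                if vp_node is np_node or not _label_is(vp_node, "VP"):
                    continue
                for np_ent, vp_ent in ((e1, e2), (e2, e1)):
                    if not np_node.dominates_span(*np_ent.span):
                        continue
                    if not vp_node.dominates_span(*vp_ent.span):
                        continue
                    out.append(
                        NpVpStructure(
                            parent=parent,
                            np_node=np_node,
                            vp_node=vp_node,
                            np_entity=np_ent,
                            vp_entity=vp_ent,
                            np_direct=tree.minimal_dominating(*np_ent.span) is np_node,
                            vp_direct=tree.minimal_dominating(*vp_ent.span) is vp_node,
                            is_full_sentence=parent is tree.root,
                        )
                    )
    return out


def apply_rp2(
    structures: Sequence[NpVpStructure],
    sentence: AnnotatedSentence,
    lexicon: InteractionLexicon,
) -> list[RelationCandidate]:
    """RP2: emit a candidate per structure whose VP subtree contains an
    interaction word; one relation per (pair, word) after deduplication."""
    seen = set()
    out = []
    for struct in structures:
        lo, hi = struct.vp_node.leaf_span()
        for idx in range(lo, hi + 1):
            token = sentence.tokens[idx - 1]
            if any(e.start <= idx <= e.end for e in sentence.entities):
                continue
            if not lexicon.matches(token.lemma, token.surface):
                continue
            a, b = sorted((struct.np_entity, struct.vp_entity), key=lambda e: e.start)
            pair = EntityPairInstance(sentence.sid, a, b)
            dedup = (pair.key, idx)
            if dedup in seen:
                continue
            seen.add(dedup)
            out.append(
                RelationCandidate(
                    pair=pair,
                    word_index=idx,
                    word_lemma=token.lemma,
                    rule="RP",
                    evidence=(
                        struct.parent.label,
                        struct.np_node.leaf_span(),
                        struct.vp_node.leaf_span(),
                    ),
                )
            )
    return out
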