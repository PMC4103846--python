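"""Semi-supervised K-nearest-neighbor classification of entity-pair
instances, with rule-based error correction.

Each instance is represented by the lemma sequence of the shortest
dependency path between its two entities (entity tokens masked), compared
by normalized edit similarity.  Labels propagate over the KNN graph by
clamped iterative neighborhood averaging from a small labeled seed set; the
rule extractors (RD/RP) then correct the propagated labels, either by
overriding every rule-extracted instance to positive or by deciding only
near-tie instances.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import AnnotatedSentence, EntityPairInstance
from .dependency import entity_anchor, shortest_dependency_path

__all__ = [
    "KnnConfig",
    "ENTITY_MASK",
    "path_representation",
    "edit_distance",
    "edit_similarity",
    "knn_classify",
    "correct_with_rules",
    "random_split",
]

ENTITY_MASK = "ENTITY"


@dataclass(frozen=True)
class KnnConfig:
    """Neighbor count, labeling scheme, and correction policy."""

    k: int = 5
    labeled_fraction: float = 0.2
    seed: int = 0
    correction_mode: str = "override"   # override | fill_unknown
    margin: float = 0.05                # fill_unknown: |score - 0.5| <= margin
    tol: float = 1e-6
    max_iter: int = 1000
    hard_knn: bool = False              # majority vote of labeled neighbors only

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.correction_mode not in ("override", "fill_unknown"):
            raise ValueError(f"unknown correction_mode {self.correction_mode!r}")


def path_representation(
    sentence: AnnotatedSentence,
    pair: EntityPairInstance,
) -> tuple[str, ...]:
    """Lemma sequence along the shortest dependency path between the pair's
    anchor tokens; entity tokens masked.  Empty tuple when disconnected."""
    g = sentence.dependencies
    if g is None:
        raise ValueError(f"{sentence.sid}: no dependency graph attached")
    path = shortest_dependency_path(g, entity_anchor(pair.m1), entity_anchor(pair.m2))
    if path is None:
        return ()
    reps = []
    for idx in path:
        if any(e.start <= idx <= e.end for e in (pair.m1, pair.m2)):
            reps.append(ENTITY_MASK)
        else:
            reps.append(sentence.tokens[idx - 1].lemma)
    return tuple(reps)


def edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Token-level Levenshtein distance (unit insert/delete/substitute costs)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, start=1):
        cur = [i]
        for j, tb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ta != tb)))
        prev = cur
    return prev[-1]


def edit_similarity(a: Sequence[str], b: Sequence[str]) -> float:
    """1 - edit_distance / max length, in [0, 1]; two empty sequences -> 1."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - edit_distance(a, b) / m


def _knn_graph(instances: Sequence[Sequence[str]], k: int) -> list[list[int]]:
    """Symmetrized K-nearest-neighbor adjacency under edit similarity.

    Each node links to its k most similar other nodes (ties broken by
    index); the union of directed choices gives the undirected neighborhood.
    """
    n = len(instances)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = edit_similarity(instances[i], instances[j])
            sim[i, j] = sim[j, i] = s
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (-sim[i, j], j))
        for j in order[:k]:
            neighbors[i].add(j)
            neighbors[j].add(i)
    return [sorted(ns) for ns in neighbors]


def knn_classify(
    instances: Sequence[Sequence[str]],
    labels: dict[int, str],
    cfg: KnnConfig = KnnConfig(),
) -> tuple[list[str], np.ndarray, int]:
    """Propagate partial labels over the KNN graph.

    ``labels`` maps instance index -> "positive"/"negative" for the seed
    set.  Scores start at 1 (positive), 0 (negative), 0.5 (unlabeled) and
    are iteratively replaced by the neighborhood mean, with labeled nodes
    clamped, until the maximum change falls below ``cfg.tol``.  Returns
    (labels, final scores, iterations); score > 0.5 -> positive, ties ->
    negative.
    """
    n = len(instances)
    if cfg.k >= n:
        raise ValueError(f"K={cfg.k} must be < instance count {n}")
    classes = set(labels.values())
    if not classes <= {"positive", "negative"}:
        raise ValueError(f"unexpected labels: {classes}")
    neighbors = _knn_graph(instances, cfg.k)

    if cfg.hard_knn:
        scores = np.full(n, 0.5)
        out = []
        for i in range(n):
            if i in labels:
                out.append(labels[i])
                scores[i] = 1.0 if labels[i] == "positive" else 0.0
                continue
            votes = [labels[j] for j in neighbors[i] if j in labels]
            pos = sum(v == "positive" for v in votes)
            score = pos / len(votes) if votes else 0.5
            scores[i] = score
            out.append("positive" if score > 0.5 else "negative")
        return out, scores, 0

    scores = np.full(n, 0.5)
    for i, lab in labels.items():
        scores[i] = 1.0 if lab == "positive" else 0.0
    clamped = np.array([i in labels for i in range(n)])
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        new = scores.copy()
        for i in range(n):
            if clamped[i] or not neighbors[i]:
                continue
            new[i] = scores[neighbors[i]].mean()
        delta = float(np.abs(new - scores).max())
        scores = new
        if delta < cfg.tol:
            break
    out = [
        labels[i] if i in labels else ("positive" if scores[i] > 0.5 else "negative")
        for i in range(n)
    ]
    return out, scores, iterations


def correct_with_rules(
    knn_labels: Sequence[str],
    scores: Sequence[float],
    rule_positive: set[int],
    cfg: KnnConfig = KnnConfig(),
) -> list[str]:
    """Correct propagated labels with the rule extractors' output.

    override: every rule-extracted instance becomes positive (never demotes).
    fill_unknown: rules decide only instances whose score is within
    ``cfg.margin`` of the 0.5 tie point; others keep their KNN label.
    """
    out = list(knn_labels)
    for i in rule_positive:
        if cfg.correction_mode == "override":
            out[i] = "positive"
        else:
            if abs(scores[i] - 0.5) <= cfg.margin:
                out[i] = "positive"
    return out


def random_split(
    n: int,
    labeled_ratio: float,
    seed: int,
    min_labeled: int = 1,
) -> tuple[list[int], list[int]]:
    """Random labeled/unlabeled index split at the given labeled ratio."""
    if not 0 < labeled_ratio < 1:
        raise ValueError("labeled_ratio must be in (0, 1)")
    rng = random.Random(seed)
    indices = list(range(n))
    rng.shuffle(indices)
    cut = max(min_labeled, int(round(labeled_ratio * n)))
    return sorted(indices[:cut]), sorted(indices[cut:])
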