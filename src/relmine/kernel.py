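"""Polynomial-kernel similarity over pattern term vectors, and greedy
average-linkage clustering of the pattern set.

Patterns are bags of terms.  The base kernel between two patterns is the
inner product of their term-frequency vectors; the polynomial kernel raises
it to (<u,v> + c)^d, trading off higher-order against lower-order term
co-occurrence.  Clustering pops patterns in descending-frequency order and
merges each into the existing cluster with the highest average similarity,
provided that average exceeds a threshold theta; otherwise the pattern seeds
a new cluster.  Theta is chosen from the similarity histogram: the lower
limit of the first interval whose pair count collapses to at most a set
fraction (default 20%) of the previous interval's.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .patterns import CandidatePattern

__all__ = [
    "KernelParams",
    "ClusteringConfig",
    "PKMatrix",
    "DegenerateHistogramError",
    "term_vector",
    "base_kernel",
    "polynomial_kernel",
    "kernel_matrix",
    "select_threshold",
    "cluster_patterns",
    "write_clusters",
]


@dataclass(frozen=True)
class KernelParams:
    """Polynomial-kernel parameters: degree ``d`` and offset ``c``."""

    d: int = 2
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"degree d must be >= 1, got {self.d}")
        if self.c < 0:
            raise ValueError(f"constant c must be >= 0, got {self.c}")


@dataclass(frozen=True)
class ClusteringConfig:
    """Threshold-selection and clustering configuration."""

    theta: float | None = None     # None -> select heuristically
    n_intervals: int = 10
    drop_fraction: float = 0.20
    scan_high_to_low: bool = False

    def __post_init__(self) -> None:
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.n_intervals < 2:
            raise ValueError("n_intervals must be >= 2")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")


class DegenerateHistogramError(ValueError):
    """All off-diagonal similarities are equal; no drop interval exists.

    Carries the stated fallback threshold (the median similarity) so callers
    that prefer to continue can use it.
    """

    def __init__(self, fallback: float):
        super().__init__(
            "degenerate similarity histogram (all off-diagonal similarities "
            f"equal); fallback threshold = median similarity {fallback!r}"
        )
        self.fallback = fallback


def term_vector(pattern: CandidatePattern | Sequence[str]) -> Counter:
    """Bag-of-terms vector of a pattern (term -> count)."""
    tokens = pattern.tokens if isinstance(pattern, CandidatePattern) else pattern
    if not tokens:
        raise ValueError("term_vector of an empty pattern")
    return Counter(tokens)


def base_kernel(u: Counter, v: Counter) -> float:
    """Inner product of two term-frequency vectors."""
    if len(v) < len(u):
        u, v = v, u
    return float(sum(count * v[t] for t, count in u.items()))


def polynomial_kernel(u: Counter, v: Counter, kp: KernelParams = KernelParams()) -> float:
    """(<u, v> + c)^d."""
    return (base_kernel(u, v) + kp.c) ** kp.d


@dataclass(frozen=True)
class PKMatrix:
    """Symmetric n x n polynomial-kernel matrix over a sorted pattern list."""

    values: np.ndarray
    keys: tuple[str, ...]  # frequency_key per row/column

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal kernel values as a flat array."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def kernel_matrix(
    patterns: Sequence[CandidatePattern],
    kp: KernelParams = KernelParams(),
) -> PKMatrix:
    """Pairwise polynomial-kernel matrix for a (frequency-sorted) pattern list."""
    vocab: dict[str, int] = {}
    for pat in patterns:
        for term in pat.tokens:
            vocab.setdefault(term, len(vocab))
    counts = np.zeros((len(patterns), max(len(vocab), 1)))
    for i, pat in enumerate(patterns):
        for term, cnt in Counter(pat.tokens).items():
            counts[i, vocab[term]] = cnt
    gram = (counts @ counts.T + kp.c) ** kp.d
    return PKMatrix(gram, tuple(p.frequency_key for p in patterns))


def select_threshold(matrix: PKMatrix, cfg: ClusteringConfig = ClusteringConfig()) -> float:
    """Choose theta from the histogram of pairwise similarities.

    Builds ``n_intervals`` equal-width intervals over [0, max off-diagonal
    similarity], counts pair similarities per interval, and scans for the
    first interval whose count drops to <= ``drop_fraction`` of the previous
    (non-empty) interval's count; theta is that interval's lower limit.  With
    no qualifying drop, the top interval's lower limit is returned.
    """
    if matrix.n == 0:
        raise ValueError("empty kernel matrix")
    sims = matrix.off_diagonal()
    if sims.size == 0:
        # single pattern: nothing to merge, any non-negative theta works
        return 0.0
    if sims.size == 1:
        return float(sims[0])  # one pair: no histogram, theta caps at s
    smax = float(sims.max())
    if smax <= 0 or np.allclose(sims, sims[0]):
        raise DegenerateHistogramError(float(np.median(sims)))
    counts, edges = np.histogram(sims, bins=cfg.n_intervals, range=(0.0, smax))
    if cfg.scan_high_to_low:
        scan = [(i, counts[i + 1]) for i in range(cfg.n_intervals - 2, -1, -1)]
    else:
        scan = [(i, counts[i - 1]) for i in range(1, cfg.n_intervals)]
    for i, prev in scan:
        if prev > 0 and counts[i] <= cfg.drop_fraction * prev:
            return float(edges[i])
    return float(edges[-2])  # lower limit of the top interval


def cluster_patterns(
    patterns: Sequence[CandidatePattern],
    matrix: PKMatrix,
    theta: float,
) -> list[list[int]]:
    """Greedy average-linkage clustering over the sorted pattern list.

    Patterns are taken in order (the caller supplies them sorted by
    descending total frequency).  Each pattern joins the existing cluster
    with the greatest average kernel similarity if that average exceeds
    ``theta`` (ties broken toward the earliest-created cluster); otherwise it
    opens a new cluster.  Returns clusters as lists of pattern indices.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if len(patterns) != matrix.n:
        raise ValueError("pattern list and kernel matrix size mismatch")
    clusters: list[list[int]] = []
    for p in range(len(patterns)):
        best_idx = -1
        best_avg = -np.inf
        for ci, members in enumerate(clusters):
            avg = float(matrix.values[p, members].mean())
            if avg > best_avg:
                best_avg = avg
                best_idx = ci
        if best_idx >= 0 and best_avg > theta:
            clusters[best_idx].append(p)
        else:
            clusters.append([p])
    return clusters


def write_clusters(
    clusters: Sequence[Sequence[int]],
    patterns: Sequence[CandidatePattern],
    matrix: PKMatrix,
    path,
) -> None:
    """Dump clusters, one block per cluster, with average intra-cluster similarity."""
    with open(path, "w", encoding="utf-8") as fh:
        for ci, members in enumerate(clusters):
            sub = matrix.values[np.ix_(members, members)]
            if len(members) > 1:
                iu = np.triu_indices(len(members), k=1)
                avg = float(sub[iu].mean())
            else:
                avg = float("nan")
            fh.write(f"# cluster {ci}\tsize={len(members)}\tavg_sim={avg:.4f}\n")
            for m in members:
                fh.write(f"{patterns[m].frequency_key}\n")
            fh.write("\n")
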