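"""Occurrence-level precision/recall/F evaluation.

Relations are scored per individual co-mention: every (sentence, mention
pair) occurrence of an interaction counts separately ("one answer per
occurrence"), so a relation asserted twice in a document must be found
twice.  F is the harmonic mean 2pr/(p+r), with the convention that an
undefined precision or recall (empty denominator) scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["EvalReport", "f_score", "evaluate_oaod"]


def f_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when p + r == 0."""
    if p + r <= 0:
        return 0.0
    return 2 * p * r / (p + r)


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f(self) -> float:
        return f_score(self.precision, self.recall)

    def as_percentages(self) -> tuple[float, float, float]:
        """(P, R, F) scaled x100 and rounded to two decimals."""
        return (
            round(100 * self.precision, 2),
            round(100 * self.recall, 2),
            round(100 * self.f, 2),
        )

    def __str__(self) -> str:
        p, r, f = self.as_percentages()
        return f"P={p:.2f} R={r:.2f} F={f:.2f} (tp={self.tp} fp={self.fp} fn={self.fn})"


def evaluate_oaod(predicted: Iterable, gold: Iterable) -> EvalReport:
    """Score occurrence-keyed relation sets.

    Both inputs are iterables of hashable occurrence keys — canonically
    ``(sid, frozenset({id1, id2}))`` — one per mention-pair occurrence.
    """
    pred = set(predicted)
    gold = set(gold)
    tp = len(pred & gold)
    return EvalReport(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)
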