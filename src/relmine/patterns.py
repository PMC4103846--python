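"""Candidate interaction-pattern extraction and filtering.

A candidate pattern is the word sequence between two co-mentioned entities,
kept only when the entities are close enough (window bound), not separated
by a negation word, and non-empty after filtering out stopwords, non-English
tokens (digits, Greek letters, single characters) and entity names.
Patterns are keyed on their filtered lemma sequence, so inflectional
variants of the same context aggregate into one pattern type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .corpus import AnnotatedSentence, EntityPairInstance, Token

__all__ = [
    "FilterConfig",
    "CandidatePattern",
    "default_stopwords",
    "load_stopwords",
    "filter_tokens",
    "extract_candidate",
    "build_pattern_set",
    "write_pattern_set",
]

NEGATION_WORDS = frozenset({"no", "not", "neither"})

# a token counts as English here only if made of Latin letters/hyphens and
# longer than one character — this drops numbers, Greek symbols and formula
# fragments that carry no lexical interaction signal
_ENGLISH_RE = re.compile(r"^[A-Za-z-]{2,}$")


def load_stopwords(path) -> frozenset[str]:
    """Load a one-word-per-line stopword file (lower-cased)."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip().lower() for w in fh if w.strip())


def default_stopwords() -> frozenset[str]:
    text = resources.files("relmine.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class FilterConfig:
    """Window and filtering configuration for pattern extraction."""

    window: int = 10
    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    negation_words: frozenset[str] = NEGATION_WORDS

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")

    def is_nonenglish(self, surface: str) -> bool:
        return not _ENGLISH_RE.match(surface)


@dataclass(frozen=True)
class CandidatePattern:
    """A filtered inter-entity token sequence (the clustering unit)."""

    tokens: tuple[str, ...]            # filtered lemmas, order preserved
    pos: tuple[str, ...]               # coarse POS per token, aligned
    source: tuple[str, frozenset]      # (sentence id, mention-id pair)

    @property
    def frequency_key(self) -> str:
        return " ".join(self.tokens)


def filter_tokens(
    tokens: Sequence[Token],
    cfg: FilterConfig,
    entity_names: frozenset[str] = frozenset(),
) -> list[Token]:
    """Drop stopwords, non-English tokens and entity names; keep order."""
    names = {n.lower() for n in entity_names}
    out = []
    for tok in tokens:
        low = tok.surface.lower()
        if low in cfg.stopwords:
            continue
        if cfg.is_nonenglish(tok.surface):
            continue
        if low in names:
            continue
        out.append(tok)
    return out


def extract_candidate(
    sentence: AnnotatedSentence,
    pair: EntityPairInstance,
    cfg: FilterConfig,
    entity_names: Optional[frozenset[str]] = None,
) -> Optional[CandidatePattern]:
    """Extract the filtered pattern between a mention pair, or None.

    Returns None when the raw inter-entity token count exceeds the window,
    when a negation word occurs between the entities, or when filtering
    leaves nothing.  Window and negation checks run on the raw (unfiltered)
    token sequence.
    """
    if pair.sid != sentence.sid:
        raise ValueError(f"pair belongs to {pair.sid}, not {sentence.sid}")
    between = sentence.tokens[pair.m1.end : pair.m2.start - 1]
    if len(between) > cfg.window:
        return None
    if any(t.surface.lower() in cfg.negation_words for t in between):
        return None
    if entity_names is None:
        entity_names = frozenset(e.name for e in sentence.entities)
    kept = filter_tokens(between, cfg, entity_names)
    if not kept:
        return None
    return CandidatePattern(
        tokens=tuple(t.lemma for t in kept),
        pos=tuple(t.pos for t in kept),
        source=(sentence.sid, frozenset({pair.m1.id, pair.m2.id})),
    )


def build_pattern_set(
    corpus: Sequence[AnnotatedSentence],
    cfg: Optional[FilterConfig] = None,
) -> list[tuple[CandidatePattern, int]]:
    """Aggregate candidate patterns over all entity pairs in the corpus.

    Patterns are keyed by their filtered lemma sequence; the returned list
    is sorted by total frequency descending (ties broken lexicographically
    by key, for a deterministic clustering order).
    """
    if cfg is None:
        cfg = FilterConfig()
    by_key: dict[str, tuple[CandidatePattern, int]] = {}
    for sentence in corpus:
        names = frozenset(e.name for e in sentence.entities)
        for pair in sentence.entity_pairs():
            cand = extract_candidate(sentence, pair, cfg, names)
            if cand is None:
                continue
            key = cand.frequency_key
            if key in by_key:
                first, count = by_key[key]
                by_key[key] = (first, count + 1)
            else:
                by_key[key] = (cand, 1)
    return sorted(by_key.values(), key=lambda pc: (-pc[1], pc[0].frequency_key))


def write_pattern_set(patterns: Sequence[tuple[CandidatePattern, int]], path) -> None:
    """Write (frequency_key, frequency) rows as tab-separated text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pattern\tfrequency\n")
        for pat, freq in patterns:
            fh.write(f"{pat.frequency_key}\t{freq}\n")
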