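"""Interaction-word lexicon induction from pattern clusters.

Verbs that recur within a cluster are taken as interaction verbs, reduced to
citation-form lemmas by suffix rules plus an irregular-form table, and then
extended to their derived nominal forms (associate -> association) so that
nominalized mentions of an interaction also match at extraction time.  The
morphological tables are small curated stand-ins covering the verbs common
in molecular-biology prose.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .patterns import CandidatePattern

__all__ = [
    "InteractionLexicon",
    "select_cluster_verbs",
    "normalize_verb",
    "nominalize",
    "build_lexicon",
    "load_lexicon",
    "write_lexicon",
]

# irregular inflected form -> citation lemma (biomedical verbs and common
# irregular English verbs seen in interaction contexts)
IRREGULAR_FORMS: dict[str, str] = {
    "bound": "bind",
    "binding": "bind",
    "found": "find",
    "underwent": "undergo",
    "undergone": "undergo",
    "arose": "arise",
    "arisen": "arise",
    "gave": "give",
    "given": "give",
    "took": "take",
    "taken": "take",
    "led": "lead",
    "made": "make",
    "shown": "show",
    "showed": "show",
    "seen": "see",
    "saw": "see",
    "known": "know",
    "knew": "know",
    "held": "hold",
    "kept": "keep",
    "brought": "bring",
    "broke": "break",
    "broken": "break",
    "drove": "drive",
    "driven": "drive",
    "grew": "grow",
    "grown": "grow",
    "lay": "lie",
    "lain": "lie",
    "rose": "rise",
    "risen": "rise",
    "became": "become",
    "began": "begin",
    "begun": "begin",
    "was": "be",
    "were": "be",
    "been": "be",
    "is": "be",
    "are": "be",
    "has": "have",
    "had": "have",
    "did": "do",
    "done": "do",
    "went": "go",
    "gone": "go",
    "came": "come",
    "lost": "lose",
    "met": "meet",
    "sought": "seek",
    "spliced": "splice",
    "underlay": "underlie",
    "underlain": "underlie",
}

# verb lemma -> derived nominal forms (irregular / non-suffix-predictable)
IRREGULAR_NOMINALS: dict[str, tuple[str, ...]] = {
    "bind": ("binding",),
    "block": ("blocking", "blockade"),
    "cleave": ("cleavage",),
    "splice": ("splicing",),
    "signal": ("signaling", "signalling"),
    "couple": ("coupling",),
    "cross-link": ("cross-linking",),
    "fold": ("folding",),
    "target": ("targeting",),
    "uptake": ("uptake",),
    "transcribe": ("transcription",),
    "respond": ("response",),
    "recognize": ("recognition",),
    "catalyze": ("catalysis",),
    "synthesize": ("synthesis",),
    "inhibit": ("inhibition",),
    "express": ("expression",),
    "suppress": ("suppression",),
    "repress": ("repression",),
    "induce": ("induction",),
    "reduce": ("reduction",),
    "produce": ("production",),
    "transduce": ("transduction",),
    "interact": ("interaction",),
    "grow": ("growth",),
    "secrete": ("secretion",),
    "delete": ("deletion",),
    "deplete": ("depletion",),
    "inject": ("injection",),
    "infect": ("infection",),
    "absorb": ("absorption",),
    "adsorb": ("adsorption",),
    "assemble": ("assembly",),
    "enter": ("entry",),
    "release": ("release",),
    "exchange": ("exchange",),
    "transfer": ("transfer",),
    "turn-over": ("turnover",),
    "lyse": ("lysis",),
    "fuse": ("fusion",),
    "adhere": ("adhesion",),
    "cohere": ("cohesion",),
    "divide": ("division",),
    "decide": ("decision",),
    "transmit": ("transmission",),
    "proliferate": ("proliferation",),
}

# after stripping -ed/-ing, stems with these endings take a restored final -e
_E_RESTORE_ENDINGS = (
    "at", "uc", "iz", "ys", "yz", "os", "ul", "av", "ir", "ombin",
    "leav", "ediat", "pl", "cl", "rg", "as", "us", "id", "or", "er",
)

_VOWELS = set("aeiou")


def _restore_e(stem: str) -> str:
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS and stem[-1] not in "sl":
        return stem[:-1]  # consonant doubling: stopped -> stop
    for ending in _E_RESTORE_ENDINGS:
        if stem.endswith(ending):
            return stem + "e"
    return stem


def normalize_verb(word: str) -> str:
    """Reduce an inflected verb form to its citation lemma.

    Suffix rules handle regular -s/-es/-ed/-ing inflection; an exception
    table handles irregular forms (bound -> bind).  Already-lemmatized input
    is a fixpoint.
    """
    w = word.lower()
    if w in IRREGULAR_FORMS:
        return IRREGULAR_FORMS[w]
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses") or w.endswith("xes") or w.endswith("zes") or w.endswith("ches") or w.endswith("shes"):
        return w[:-2]
    if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
        return w[:-1]
    if w.endswith("ied") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("ed") and len(w) > 4:
        stem = w[:-2]
        if stem.endswith("e"):  # e.g. agreed -> agree
            return stem
        return _restore_e(stem)
    if w.endswith("ing") and len(w) > 5:
        return _restore_e(w[:-3])
    return w


def nominalize(lemma: str) -> set[str]:
    """Derived nominal forms of a verb lemma; empty when no rule applies."""
    lem = lemma.lower()
    if lem in IRREGULAR_NOMINALS:
        return set(IRREGULAR_NOMINALS[lem])
    if lem.endswith("ate"):
        return {lem[:-1] + "ion"}        # activate -> activation
    if lem.endswith("ize") or lem.endswith("ise"):
        return {lem[:-1] + "ation"}      # stabilize -> stabilization
    if lem.endswith("ify"):
        return {lem[:-1] + "ication"}    # modify -> modification
    if lem.endswith("act") or lem.endswith("ict") or lem.endswith("ect") or lem.endswith("uct"):
        return {lem + "ion"}             # interact -> interaction
    if lem.endswith("ess"):
        return {lem + "ion"}             # process -> procession is wrong but rare
    if lem.endswith("ss") or lem.endswith("rm") or lem.endswith("gn"):
        return {lem + "ment"}            # assess -> assessment, align -> alignment
    if lem.endswith("ance") or lem.endswith("ence"):
        return set()
    return set()


@dataclass
class InteractionLexicon:
    """Induced interaction words: verb lemmas plus derived nominal forms."""

    verbs: set[str] = field(default_factory=set)
    nouns: set[str] = field(default_factory=set)
    # lemma -> list of (cluster id, in-cluster occurrence count)
    provenance: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    _noun_to_verb: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lemma in list(self.verbs) + list(self.nouns):
            if lemma != lemma.lower():
                raise ValueError(f"lexicon lemmas must be lower-case: {lemma!r}")

    @property
    def all_lemmas(self) -> frozenset[str]:
        return frozenset(self.verbs | self.nouns)

    def matches(self, token_lemma: str, token_surface: str = "") -> bool:
        """Lemma match against verbs + nouns, with surface fallback."""
        lemmas = self.all_lemmas
        if token_lemma.lower() in lemmas:
            return True
        return bool(token_surface) and token_surface.lower() in lemmas

    def verb_of_noun(self, noun: str) -> str | None:
        return self._noun_to_verb.get(noun.lower())


def select_cluster_verbs(
    clusters: Sequence[Sequence[int]],
    patterns: Sequence[CandidatePattern],
    min_count: int = 2,
) -> dict[str, list[tuple[int, int]]]:
    """Verb lemmas recurring within at least one cluster.

    A verb's in-cluster count is the number of times it occurs across the
    cluster's member pattern types.  Returns lemma -> provenance list of
    (cluster id, count) over the clusters where the count reached
    ``min_count``.  Lemmas are normalized to citation form before counting,
    so inflectional variants of one verb pool their evidence.
    """
    selected: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ci, members in enumerate(clusters):
        verb_counts: Counter = Counter()
        for m in members:
            pat = patterns[m]
            for lemma, pos in zip(pat.tokens, pat.pos):
                if pos == "verb":
                    verb_counts[normalize_verb(lemma)] += 1
        for lemma, count in verb_counts.items():
            if count >= min_count:
                selected[lemma].append((ci, count))
    return dict(selected)


def build_lexicon(
    clusters: Sequence[Sequence[int]],
    patterns: Sequence[CandidatePattern],
    min_count: int = 2,
) -> InteractionLexicon:
    """Compose verb selection, normalization and nominal extension."""
    provenance = select_cluster_verbs(clusters, patterns, min_count)
    lex = InteractionLexicon(provenance=provenance)
    for lemma in provenance:
        lex.verbs.add(lemma)
        for noun in nominalize(lemma):
            lex.nouns.add(noun)
            lex._noun_to_verb[noun] = lemma
    return lex


def write_lexicon(lexicon: InteractionLexicon, path) -> None:
    """Plain-text lexicon: one lemma per line with a V/N tag column."""
    with open(path, "w", encoding="utf-8") as fh:
        for verb in sorted(lexicon.verbs):
            fh.write(f"{verb}\tV\n")
        for noun in sorted(lexicon.nouns):
            fh.write(f"{noun}\tN\n")


def load_lexicon(path) -> InteractionLexicon:
    """Load a user-supplied lexicon file (lemma TAB V|N per line)."""
    lex = InteractionLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("V", "N"):
                raise ValueError(f"line {lineno}: expected 'lemma<TAB>V|N'")
            lemma, tag = parts[0].lower(), parts[1]
            if tag == "V":
                lex.verbs.add(lemma)
            else:
                lex.nouns.add(lemma)
                lex._noun_to_verb.setdefault(lemma, normalize_verb(lemma))
    return lex
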