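"""Synthetic corpora and hand-built worked examples.

Two fixtures make every pipeline stage testable without an external parser
or corpus:

* :func:`worked_examples` returns two fully analyzed sentences — a
  neuregulin/ErbB-receptor sentence whose dependency tree supports the
  RD1/RD2 walk-through (six distance-qualified candidates, three surviving
  the verb-position filter), and a long p53/TAF sentence whose
  p53-to-"interact" dependency path exceeds the distance bound, so only the
  constituency NP+VP rules recover its two relations.  The dependency edges
  are transcribed from the printed shortest paths of those analyses; edges
  not on any printed path attach determiners, conjuncts and modifiers
  minimally.

* :func:`generate_corpus` emits template sentences "E1 <verb> E2" with
  controlled negation, inter-entity window violations, adverbial modifiers
  and distractor verbs.  Parses are produced deterministically from the
  generating template, and gold is every pair realized with a planted
  interaction verb, un-negated and within the extraction window.  The
  defaults emulate an abstract-scale corpus: a few hundred sentences, most
  asserting an interaction, with a ~10% negation rate and ~10% long-range
  constructions.

The generator's distractor verbs are used in one stereotyped context each
(no modifier variation), mirroring how methodological verbs recur verbatim
in abstracts; interaction verbs vary their adverbial context, which is the
signal the cluster-recurrence criterion keys on.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .corpus import (
    AnnotatedSentence,
    ConstituencyTree,
    DependencyGraph,
    EntityMention,
    Token,
    coarse_pos,
    parse_bracketed,
)

__all__ = ["GeneratorParams", "worked_examples", "generate_corpus",
           "two_cluster_instances", "write_corpus_files"]


def _tok(i: int, surface: str, lemma: str | None = None, tag: str = "NN") -> Token:
    return Token(i, surface, lemma if lemma is not None else surface.lower(),
                 coarse_pos(tag), tag)


def _sentence(sid, rows, entities, gold, heads, bracketed) -> AnnotatedSentence:
    """Assemble a sentence from (surface, lemma, tag) rows plus analyses."""
    tokens = [_tok(i, s, l, t) for i, (s, l, t) in enumerate(rows, start=1)]
    sent = AnnotatedSentence(
        sid=sid,
        tokens=tokens,
        entities=[EntityMention(*e) for e in entities],
        gold_pairs={frozenset(p) for p in gold},
    )
    edges = [(h, i, rel) for i, (h, rel) in enumerate(heads, start=1)]
    sent.dependencies = DependencyGraph(len(tokens), edges)
    sent.constituents = ConstituencyTree(parse_bracketed(bracketed), len(tokens))
    return sent


def worked_examples() -> list[AnnotatedSentence]:
    """The two fully analyzed walk-through sentences (see module docstring)."""
    # --- sentence 1: neuregulin-2beta induces phosphorylation of ErbB2/3/4
    rows1 = [
        ("Recombinant", "recombinant", "JJ"),
        ("neuregulin-2beta", "neuregulin-2beta", "NN"),
        ("induces", "induce", "VBZ"),
        ("the", "the", "DT"),
        ("tyrosine", "tyrosine", "NN"),
        ("phosphorylation", "phosphorylation", "NN"),
        ("of", "of", "IN"),
        ("ErbB2", "erbb2", "NN"),
        (",", ",", ","),
        ("ErbB3", "erbb3", "NN"),
        ("and", "and", "CC"),
        ("ErbB4", "erbb4", "NN"),
        ("in", "in", "IN"),
        ("cell", "cell", "NN"),
        ("line", "line", "NN"),
        ("express", "express", "VBP"),
        ("all", "all", "DT"),
        ("of", "of", "IN"),
        ("these", "these", "DT"),
        ("erbb", "erbb", "NN"),
        ("family", "family", "NN"),
        ("receptor", "receptor", "NN"),
        (".", ".", "."),
    ]
    heads1 = [
        (2, "amod"),    # 1 Recombinant -> neuregulin-2beta
        (3, "nsubj"),   # 2 neuregulin-2beta -> induces
        (0, "root"),    # 3 induces
        (6, "det"),     # 4 the -> phosphorylation
        (6, "nn"),      # 5 tyrosine -> phosphorylation
        (3, "dobj"),    # 6 phosphorylation -> induces
        (6, "prep"),    # 7 of -> phosphorylation
        (7, "pobj"),    # 8 ErbB2 -> of
        (8, "punct"),   # 9 , -> ErbB2
        (8, "conj"),    # 10 ErbB3 -> ErbB2
        (8, "cc"),      # 11 and -> ErbB2
        (8, "conj"),    # 12 ErbB4 -> ErbB2
        (3, "prep"),    # 13 in -> induces
        (15, "nn"),     # 14 cell -> line
        (13, "pobj"),   # 15 line -> in
        (3, "dep"),     # 16 express -> induces
        (16, "dobj"),   # 17 all -> express
        (17, "prep"),   # 18 of -> all
        (22, "det"),    # 19 these -> receptor
        (22, "nn"),     # 20 erbb -> receptor
        (22, "nn"),     # 21 family -> receptor
        (18, "pobj"),   # 22 receptor -> of
        (3, "punct"),   # 23 . -> induces
    ]
    tree1 = (
        "(S (NP (JJ Recombinant) (NN neuregulin-2beta))"
        " (VP (VBZ induces)"
        "  (NP (NP (DT the) (NN tyrosine) (NN phosphorylation))"
        "   (PP (IN of) (NP (NN ErbB2) (, ,) (NN ErbB3) (CC and) (NN ErbB4))))"
        "  (PP (IN in) (NP (NN cell) (NN line)))"
        "  (SBAR (S (VP (VBP express)"
        "   (NP (NP (DT all)) (PP (IN of)"
        "    (NP (DT these) (NN erbb) (NN family) (NN receptor))))))))"
        " (. .))"
    )
    s1 = _sentence(
        "wx1",
        rows1,
        entities=[
            ("NRG2b", 2, 2, "neuregulin-2beta"),
            ("ErbB2", 8, 8, "ErbB2"),
            ("ErbB3", 10, 10, "ErbB3"),
            ("ErbB4", 12, 12, "ErbB4"),
        ],
        gold=[("NRG2b", "ErbB2"), ("NRG2b", "ErbB3"), ("NRG2b", "ErbB4")],
        heads=heads1,
        bracketed=tree1,
    )

    # --- sentence 2: p53 / TAFII40 / TAFII60, long dependency path
    rows2 = [
        ("A", "a", "DT"),
        ("double", "double", "JJ"),
        ("point", "point", "NN"),
        ("mutation", "mutation", "NN"),
        ("in", "in", "IN"),
        ("the", "the", "DT"),
        ("activation", "activation", "NN"),
        ("domain", "domain", "NN"),
        ("of", "of", "IN"),
        ("p53", "p53", "NN"),
        ("impaired", "impair", "VBD"),
        ("the", "the", "DT"),
        ("ability", "ability", "NN"),
        ("of", "of", "IN"),
        ("this", "this", "DT"),
        ("domain", "domain", "NN"),
        ("to", "to", "TO"),
        ("activate", "activate", "VB"),
        ("transcription", "transcription", "NN"),
        ("and", "and", "CC"),
        ("its", "its", "PRP$"),
        ("ability", "ability", "NN"),
        ("to", "to", "TO"),
        ("interact", "interact", "VB"),
        ("with", "with", "IN"),
        ("both", "both", "CC"),
        ("TAFII40", "tafii40", "NN"),
        ("and", "and", "CC"),
        ("TAFII60", "tafii60", "NN"),
        (".", ".", "."),
    ]
    heads2 = [
        (4, "det"),      # 1 A -> mutation
        (4, "amod"),     # 2 double -> mutation
        (4, "nn"),       # 3 point -> mutation
        (11, "nsubj"),   # 4 mutation -> impaired
        (4, "prep"),     # 5 in -> mutation
        (8, "det"),      # 6 the -> domain
        (8, "nn"),       # 7 activation -> domain
        (5, "pobj"),     # 8 domain -> in
        (8, "prep"),     # 9 of -> domain
        (9, "pobj"),     # 10 p53 -> of
        (0, "root"),     # 11 impaired
        (13, "det"),     # 12 the -> ability
        (11, "dobj"),    # 13 ability -> impaired
        (13, "prep"),    # 14 of -> ability
        (16, "det"),     # 15 this -> domain
        (14, "pobj"),    # 16 domain -> of
        (11, "xcomp"),   # 17 to -> impaired
        (17, "dep"),     # 18 activate -> to
        (17, "dep"),     # 19 transcription -> to
        (19, "cc"),      # 20 and -> transcription
        (22, "poss"),    # 21 its -> ability
        (19, "conj"),    # 22 ability -> transcription
        (24, "aux"),     # 23 to -> interact
        (22, "infmod"),  # 24 interact -> ability
        (24, "prep"),    # 25 with -> interact
        (27, "preconj"), # 26 both -> TAFII40
        (25, "pobj"),    # 27 TAFII40 -> with
        (27, "cc"),      # 28 and -> TAFII40
        (27, "conj"),    # 29 TAFII60 -> TAFII40
        (11, "punct"),   # 30 . -> impaired
    ]
    tree2 = (
        "(S (NP (NP (DT A) (JJ double) (NN point) (NN mutation))"
        "  (PP (IN in) (NP (NP (DT the) (NN activation) (NN domain))"
        "   (PP (IN of) (NP (NN p53))))))"
        " (VP (VBD impaired)"
        "  (NP (NP (DT the) (NN ability))"
        "   (PP (IN of) (NP (DT this) (NN domain)))"
        "   (S (VP (TO to) (VP (VB activate) (NP (NN transcription))))))"
        "  (CC and)"
        "  (NP (NP (PRP$ its) (NN ability))"
        "   (S (VP (TO to) (VP (VB interact)"
        "    (PP (IN with) (NP (CC both) (NN TAFII40) (CC and) (NN TAFII60))))))))"
        " (. .))"
    )
    s2 = _sentence(
        "wx2",
        rows2,
        entities=[
            ("p53", 10, 10, "p53"),
            ("TAFII40", 27, 27, "TAFII40"),
            ("TAFII60", 29, 29, "TAFII60"),
        ],
        gold=[("p53", "TAFII40"), ("p53", "TAFII60")],
        heads=heads2,
        bracketed=tree2,
    )
    return [s1, s2]


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions the synthetic corpus emulates.

    ``positive_rate`` is the fraction of sentences built around a planted
    interaction verb; of those, ``negation_rate`` are negated and
    ``window_violation_rate`` place the entities beyond the extraction
    window (both excluded from gold).  The remaining sentences use a
    distractor verb and contribute no gold pair.
    """

    n_sentences: int = 200
    n_entities: int = 30
    interaction_verbs: tuple[str, ...] = (
        "bind", "activate", "phosphorylate", "inhibit", "associate", "interact",
    )
    distractor_verbs: tuple[str, ...] = (
        "resemble", "precede", "accompany", "follow", "parallel", "concern",
    )
    negation_rate: float = 0.10
    positive_rate: float = 0.60
    window_violation_rate: float = 0.10
    modifier_rate: float = 0.50
    adverbs: tuple[str, ...] = (
        "strongly", "directly", "specifically", "weakly", "selectively", "markedly",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("negation_rate", "positive_rate", "window_violation_rate",
                     "modifier_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


_PREP_VERBS = {"associate", "interact"}  # realized as "V with E2"
_NP_CHAIN = (("extracellular", "domain"), ("cytoplasmic", "region"),
             ("terminal", "fragment"))


def _third_person(verb: str) -> str:
    if verb.endswith(("s", "x", "z", "ch", "sh")):
        return verb + "es"
    if verb.endswith("y") and verb[-2] not in "aeiou":
        return verb[:-1] + "ies"
    return verb + "s"


def _simple_sentence(sid, e1, e2, verb, adverb, negated) -> AnnotatedSentence:
    """Template: E1 [does not] [adv] V [with] E2 ."""
    lemma = verb
    prep = lemma in _PREP_VERBS
    rows: list[tuple[str, str, str]] = [(e1, e1.lower(), "NN")]
    heads: list[tuple[int, str]] = []
    if negated:
        rows += [("does", "do", "VBZ"), ("not", "not", "RB")]
    if adverb:
        rows.append((adverb, adverb, "RB"))
    verb_idx = len(rows) + 1
    rows.append((_third_person(lemma) if not negated else lemma,
                 lemma, "VBZ" if not negated else "VB"))
    if prep:
        rows.append(("with", "with", "IN"))
    e2_idx = len(rows) + 1
    rows.append((e2, e2.lower(), "NN"))
    rows.append((".", ".", "."))

    heads = [(0, "")] * len(rows)
    heads[0] = (verb_idx, "nsubj")
    pos = 2
    if negated:
        heads[1] = (verb_idx, "aux")
        heads[2] = (verb_idx, "neg")
        pos = 4
    if adverb:
        heads[pos - 1] = (verb_idx, "advmod")
    heads[verb_idx - 1] = (0, "root")
    if prep:
        heads[verb_idx] = (verb_idx, "prep")          # with -> V
        heads[e2_idx - 1] = (verb_idx + 1, "pobj")    # E2 -> with
    else:
        heads[e2_idx - 1] = (verb_idx, "dobj")
    heads[-1] = (verb_idx, "punct")

    vp_parts = []
    if negated:
        vp_parts.append("(VBZ does) (RB not)")
    if adverb:
        vp_parts.append(f"(ADVP (RB {adverb}))")
    vtag = "VB" if negated else "VBZ"
    obj = f"(PP (IN with) (NP (NN {e2})))" if prep else f"(NP (NN {e2}))"
    vp_parts.append(f"({vtag} {rows[verb_idx - 1][0]}) {obj}")
    tree = f"(S (NP (NN {e1})) (VP {' '.join(vp_parts)}) (. .))"

    sent = AnnotatedSentence(
        sid=sid,
        tokens=[_tok(i, s, l, t) for i, (s, l, t) in enumerate(rows, start=1)],
        entities=[EntityMention("E1", 1, 1, e1), EntityMention("E2", e2_idx, e2_idx, e2)],
        gold_pairs=set(),
    )
    sent.dependencies = DependencyGraph(
        len(rows), [(h, i, rel) for i, (h, rel) in enumerate(heads, start=1)]
    )
    sent.constituents = ConstituencyTree(parse_bracketed(tree), len(rows))
    return sent


def _long_range_sentence(sid, e1, e2, verb) -> AnnotatedSentence:
    """Template with a 13-token prepositional chain between the entities,
    exceeding the default 10-token window and the dependency-distance bound."""
    rows: list[tuple[str, str, str]] = [(e1, e1.lower(), "NN"),
                                        (_third_person(verb), verb, "VBZ")]
    heads: list[tuple[int, str]] = [(2, "nsubj"), (0, "root")]
    np_heads = []
    attach = 2  # current attachment site for "of"
    for adj, noun in _NP_CHAIN:
        det_i = len(rows) + 1
        rows += [("the", "the", "DT"), (adj, adj, "JJ"), (noun, noun, "NN")]
        noun_i = det_i + 2
        if attach == 2:
            heads += [(noun_i, "det"), (noun_i, "amod"), (2, "dobj")]
        else:
            heads += [(noun_i, "det"), (noun_i, "amod"), (attach, "pobj")]
        of_i = len(rows) + 1
        rows.append(("of", "of", "IN"))
        heads.append((noun_i, "prep"))
        attach = of_i
        np_heads.append(noun_i)
    e2_i = len(rows) + 1
    rows.append((e2, e2.lower(), "NN"))
    heads.append((attach, "pobj"))
    rows.append((".", ".", "."))
    heads.append((2, "punct"))

    inner = f"(NP (NN {e2}))"
    for adj, noun in reversed(_NP_CHAIN):
        inner = f"(NP (NP (DT the) (JJ {adj}) (NN {noun})) (PP (IN of) {inner}))"
    tree = f"(S (NP (NN {e1})) (VP (VBZ {rows[1][0]}) {inner}) (. .))"

    sent = AnnotatedSentence(
        sid=sid,
        tokens=[_tok(i, s, l, t) for i, (s, l, t) in enumerate(rows, start=1)],
        entities=[EntityMention("E1", 1, 1, e1), EntityMention("E2", e2_i, e2_i, e2)],
        gold_pairs=set(),
    )
    sent.dependencies = DependencyGraph(
        len(rows), [(h, i, rel) for i, (h, rel) in enumerate(heads, start=1)]
    )
    sent.constituents = ConstituencyTree(parse_bracketed(tree), len(rows))
    return sent


def generate_corpus(params: GeneratorParams) -> list[AnnotatedSentence]:
    """Generate an analyzed corpus with gold relations (see class docstring)."""
    rng = random.Random(params.seed)
    names = [f"PROT{i + 1}" for i in range(params.n_entities)]
    sentences = []
    for i in range(params.n_sentences):
        sid = f"syn{i:04d}"
        e1, e2 = rng.sample(names, 2)
        if rng.random() < params.positive_rate:
            verb = rng.choice(params.interaction_verbs)
            u = rng.random()
            if u < params.negation_rate:
                sent = _simple_sentence(sid, e1, e2, verb, None, negated=True)
            elif u < params.negation_rate + params.window_violation_rate:
                sent = _long_range_sentence(sid, e1, e2, verb)
            else:
                adverb = (rng.choice(params.adverbs)
                          if rng.random() < params.modifier_rate else None)
                sent = _simple_sentence(sid, e1, e2, verb, adverb, negated=False)
                sent.gold_pairs = {frozenset({"E1", "E2"})}
        else:
            verb = rng.choice(params.distractor_verbs)
            sent = _simple_sentence(sid, e1, e2, verb, None, negated=False)
        sentences.append(sent)
    return sentences


def two_cluster_instances(
    n: int = 200,
    seed: int = 0,
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Two well-separated families of dependency-path representations.

    Positive instances are short verb-mediated paths (ENTITY, [adv,] verb,
    ENTITY); negatives are longer apposition-like paths through a noun
    chain.  Used to exercise KNN label propagation.
    """
    rng = random.Random(seed)
    verbs = ("bind", "activate", "phosphorylate")
    advs = ("strongly", "directly", "weakly")
    nouns = ("sample", "specimen", "extract")
    instances: list[tuple[str, ...]] = []
    labels: list[str] = []
    for _ in range(n):
        if rng.random() < 0.5:
            rep = ["ENTITY"]
            if rng.random() < 0.5:
                rep.append(rng.choice(advs))
            rep += [rng.choice(verbs), "ENTITY"]
            labels.append("positive")
        else:
            rep = ["ENTITY", rng.choice(nouns), "of", rng.choice(nouns),
                   "alongside", "ENTITY"]
            labels.append("negative")
        instances.append(tuple(rep))
    return instances, labels


def write_corpus_files(sentences, prefix) -> tuple[str, str, str]:
    """Write the three standard files (JSONL sentences, CoNLL-U, bracketed
    trees) for a fully analyzed corpus; returns the three paths."""
    from .corpus import write_sentences

    sent_path = f"{prefix}.jsonl"
    conllu_path = f"{prefix}.conllu"
    trees_path = f"{prefix}.trees"
    write_sentences(sentences, sent_path)
    with open(conllu_path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(f"# sent_id = {s.sid}\n")
            g = s.dependencies
            rel_of = {dep: (head, rel) for head, dep, rel in g.edges}
            for t in s.tokens:
                head, rel = rel_of.get(t.index, (0, "root"))
                fh.write(
                    f"{t.index}\t{t.surface}\t{t.lemma}\t_\t{t.tag}\t_\t{head}\t{rel}\t_\t_\n"
                )
            fh.write("\n")
    with open(trees_path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(_unparse(s.constituents.root) + "\n")
    return sent_path, conllu_path, trees_path


def _unparse(node) -> str:
    if node.is_leaf:
        return node.label
    inner = " ".join(_unparse(c) for c in node.children)
    return f"({node.label} {inner})"
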