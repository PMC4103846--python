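"""End-to-end orchestration of the unsupervised and semi-supervised
relation-extraction pipelines.

The unsupervised route is: candidate-pattern extraction -> polynomial-kernel
clustering -> interaction-lexicon induction -> dependency rules (RD1, RD2)
-> constituency rules (RP1, RP2) on the pairs the dependency rules missed ->
union of the two rule outputs.  The semi-supervised route first classifies
entity-pair instances by KNN label propagation and then corrects the labels
with the rule output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .corpus import AnnotatedSentence, EntityPairInstance
from .dependency import RelationCandidate, apply_rd1, apply_rd2
from .evaluate import EvalReport, evaluate_oaod
from .kernel import (
    ClusteringConfig,
    DegenerateHistogramError,
    KernelParams,
    cluster_patterns,
    kernel_matrix,
    select_threshold,
)
from .lexicon import InteractionLexicon, build_lexicon
from .patterns import FilterConfig, build_pattern_set
from .phrase import apply_rp2, find_np_vp
from .semisup import KnnConfig, correct_with_rules, knn_classify, path_representation, random_split

logger = logging.getLogger("relmine")

__all__ = ["PipelineConfig", "PipelineResult", "induce_lexicon", "extract_relations",
           "run_unsupervised", "run_semi_supervised", "ablate", "ABLATION_MODES"]

ABLATION_MODES = ("RD1", "RD1+RD2", "RP", "RD+RP")


@dataclass(frozen=True)
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    kernel: KernelParams = field(default_factory=KernelParams)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    min_verb_count: int = 2
    max_dd: int = 4
    rp_independent: bool = False   # run RP on all pairs, not just RD leftovers
    knn: KnnConfig = field(default_factory=KnnConfig)
    include_self_pairs: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    relations: list[RelationCandidate]
    lexicon: Optional[InteractionLexicon]
    theta: Optional[float]
    n_clusters: Optional[int]
    report: Optional[EvalReport]

    @property
    def predicted_keys(self) -> set:
        return {c.key for c in self.relations}


def induce_lexicon(
    corpus: Sequence[AnnotatedSentence],
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[InteractionLexicon, float, int]:
    """Pattern extraction + clustering + lexicon induction.

    Returns (lexicon, theta, number of clusters).
    """
    pattern_set = build_pattern_set(corpus, cfg.filters)
    logger.info("pattern types: %d", len(pattern_set))
    if not pattern_set:
        return InteractionLexicon(), 0.0, 0
    patterns = [p for p, _ in pattern_set]
    matrix = kernel_matrix(patterns, cfg.kernel)
    if cfg.clustering.theta is not None:
        theta = cfg.clustering.theta
    else:
        try:
            theta = select_threshold(matrix, cfg.clustering)
        except DegenerateHistogramError as err:
            logger.warning("degenerate similarity histogram; using median fallback")
            theta = err.fallback
    clusters = cluster_patterns(patterns, matrix, theta)
    logger.info("theta=%.4f clusters=%d", theta, len(clusters))
    lexicon = build_lexicon(clusters, patterns, cfg.min_verb_count)
    logger.info("lexicon: %d verbs, %d nouns", len(lexicon.verbs), len(lexicon.nouns))
    return lexicon, theta, len(clusters)


def _dedupe(candidates: Sequence[RelationCandidate]) -> list[RelationCandidate]:
    """One relation per occurrence key, keeping the lowest-distance evidence."""
    best: dict = {}
    for cand in candidates:
        key = cand.key
        if key not in best or (cand.dd1 + cand.dd2) < (best[key].dd1 + best[key].dd2):
            best[key] = cand
    return list(best.values())


def extract_relations(
    corpus: Sequence[AnnotatedSentence],
    lexicon: InteractionLexicon,
    cfg: PipelineConfig = PipelineConfig(),
    mode: str = "RD+RP",
) -> list[RelationCandidate]:
    """Run the selected rule subset over the corpus.

    Modes: RD1 (distance rule only), RD1+RD2 (both dependency rules), RP
    (constituency rules alone), RD+RP (dependency rules, then constituency
    rules on the pairs they missed — the full unsupervised extractor).
    """
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {ABLATION_MODES}")
    out: list[RelationCandidate] = []
    for sentence in corpus:
        rd: list[RelationCandidate] = []
        if mode != "RP":
            rd = apply_rd1(sentence, lexicon, cfg.max_dd)
            if mode != "RD1":
                rd = apply_rd2(rd, sentence)
        rp: list[RelationCandidate] = []
        if mode in ("RP", "RD+RP"):
            covered = {c.key for c in rd}
            for pair in sentence.entity_pairs(include_self_name=cfg.include_self_pairs):
                if not cfg.rp_independent and mode == "RD+RP" and pair.key in covered:
                    continue
                structures = find_np_vp(sentence.constituents, pair.m1, pair.m2)
                rp.extend(apply_rp2(structures, sentence, lexicon))
        out.extend(_dedupe(rd + rp))
    return out


def run_unsupervised(
    corpus: Sequence[AnnotatedSentence],
    cfg: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Full unsupervised pipeline; evaluates against gold when present."""
    lexicon, theta, n_clusters = induce_lexicon(corpus, cfg)
    relations = extract_relations(corpus, lexicon, cfg, mode="RD+RP")
    report = _maybe_evaluate(corpus, {c.key for c in relations})
    return PipelineResult(relations, lexicon, theta, n_clusters, report)


def ablate(
    corpus: Sequence[AnnotatedSentence],
    cfg: PipelineConfig,
    mode: str,
    lexicon: Optional[InteractionLexicon] = None,
) -> tuple[list[RelationCandidate], Optional[EvalReport]]:
    """Run one rule subset and score it against gold."""
    if lexicon is None:
        lexicon, _, _ = induce_lexicon(corpus, cfg)
    relations = extract_relations(corpus, lexicon, cfg, mode=mode)
    return relations, _maybe_evaluate(corpus, {c.key for c in relations})


def _gold_keys(corpus: Sequence[AnnotatedSentence]) -> set:
    return {(s.sid, pair) for s in corpus for pair in s.gold_pairs}


def _maybe_evaluate(corpus: Sequence[AnnotatedSentence], predicted: set) -> Optional[EvalReport]:
    gold = _gold_keys(corpus)
    if not gold and not any(s.gold_pairs for s in corpus):
        return None
    return evaluate_oaod(predicted, gold)


def run_semi_supervised(
    corpus: Sequence[AnnotatedSentence],
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[PipelineResult, list[tuple[EntityPairInstance, str]]]:
    """KNN label propagation from a random labeled split, corrected by rules.

    Gold pairs provide the seed labels for the labeled subset of instances
    (positive if the pair is gold, negative otherwise).  Returns the
    pipeline result scored on the corrected labels, plus per-instance
    (pair, label) assignments.
    """
    pairs: list[EntityPairInstance] = []
    reps = []
    for sentence in corpus:
        for pair in sentence.entity_pairs(include_self_name=cfg.include_self_pairs):
            pairs.append(pair)
            reps.append(path_representation(sentence, pair))
    if len(pairs) < 2:
        raise ValueError("semi-supervised run needs at least 2 entity-pair instances")
    gold = _gold_keys(corpus)
    labeled_idx, _ = random_split(len(pairs), cfg.knn.labeled_fraction, cfg.knn.seed)
    labels = {
        i: ("positive" if pairs[i].key in gold else "negative") for i in labeled_idx
    }
    if len(set(labels.values())) < 2:
        raise ValueError("labeled split must contain both classes; change seed or ratio")
    knn_labels, scores, iters = knn_classify(reps, labels, cfg.knn)
    logger.info("label propagation converged in %d iterations", iters)

    unsup = run_unsupervised(corpus, cfg)
    rule_positive = {
        i for i, pair in enumerate(pairs) if pair.key in unsup.predicted_keys
    }
    corrected = correct_with_rules(knn_labels, scores, rule_positive, cfg.knn)
    predicted = {pairs[i].key for i, lab in enumerate(corrected) if lab == "positive"}
    report = _maybe_evaluate(corpus, predicted)
    result = PipelineResult(unsup.relations, unsup.lexicon, unsup.theta,
                            unsup.n_clusters, report)
    return result, list(zip(pairs, corrected))
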