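"""Induce an interaction-word lexicon from an unlabeled corpus.

Generates a synthetic 200-sentence corpus, extracts the filtered
inter-entity patterns, clusters them with the polynomial kernel, and
selects the verbs that recur within a cluster.  The planted interaction
verbs should be recovered and the stereotyped distractor verbs left out;
the lexicon is then extended to derived nouns (bind -> binding).
"""

from relmine import PipelineConfig, build_pattern_set, induce_lexicon
from relmine.synthetic import GeneratorParams, generate_corpus

params = GeneratorParams(seed=42)
corpus = generate_corpus(params)
patterns = build_pattern_set(corpus)
print(f"corpus: {len(corpus)} sentences, {len(patterns)} pattern types")
print("most frequent patterns:",
      ", ".join(f"'{p.frequency_key}' x{f}" for p, f in patterns[:5]))

lexicon, theta, n_clusters = induce_lexicon(corpus, PipelineConfig())
print(f"clustering threshold theta={theta:.2f}, {n_clusters} clusters")
print("induced verbs:", sorted(lexicon.verbs))
print("derived nouns:", sorted(lexicon.nouns))
planted = set(params.interaction_verbs)
print(f"planted-verb recall: {len(lexicon.verbs & planted)}/{len(planted)}, "
      f"distractors admitted: {sorted(lexicon.verbs & set(params.distractor_verbs))}")
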