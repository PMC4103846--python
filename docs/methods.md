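# Methods

## Pattern extraction

A candidate pattern is the raw token sequence strictly between two entity
mentions in one sentence. Three gates apply, in order:

1. **Window** — the raw (pre-filter) inter-entity token count must not
   exceed the window (default 10). The window is measured on raw tokens
   because the filter removes function words that still contribute to
   surface distance.
2. **Negation** — a pattern containing *no*, *not* or *neither* between
   the entities is pruned outright; negated co-mentions assert the absence
   of an interaction.
3. **Filtering** — stopwords (a ~150-word function-word list shipped in
   `relmine/data/stopwords.txt`, configurable by file), tokens with any
   character outside `A–Z a–z -` or of length 1 (numbers, Greek letters,
   formula fragments), and tokens equal to any entity name in the sentence
   are removed. A pattern empty after filtering is discarded.

Patterns are keyed on their filtered **lemma** sequence, so inflectional
variants of one context aggregate into a single pattern type; frequencies
count occurrences over all entity pairs. Ties in the descending-frequency
sort are broken lexicographically so the clustering input order is
deterministic.

## Kernel and clustering

Term vectors are raw bags of lemmas (no tf-idf or normalization: the
similarity is the polynomial kernel exactly as defined,
K(u,v) = (⟨u,v⟩ + c)^d). Degree d = 2 and offset c = 1 — the standard
inhomogeneous quadratic kernel — are package defaults and fully
configurable; with c > 0 even disjoint patterns have similarity c^d, which
the threshold must (and does) sit above.

The greedy clustering consumes patterns most-frequent-first; each pattern
merges into the cluster with the highest **average** kernel similarity when
that average strictly exceeds θ, ties going to the earliest-created
cluster, otherwise it seeds a new cluster. The procedure is deterministic
given the input order; a straight-line re-implementation of the same steps
serves as the test oracle, and implementation and oracle agree on hundreds
of random instances.

θ is selected from the histogram of upper-triangle off-diagonal kernel
values (self-similarities are excluded: θ gates pattern-to-cluster merges,
which never compare a pattern with itself). The range [0, max similarity]
is cut into `n_intervals` equal bins (default 10; the count is a package
choice, configurable) and scanned from the lowest bin upward; θ is the
lower limit of the first bin whose count drops to ≤ 20% of its predecessor
(`drop_fraction`, configurable), falling back to the top bin's lower limit
when no such drop exists. The scan direction is a genuine design choice:
scanning upward places θ at the first sparsification of the similarity
distribution, which separates incidental (disjoint-support) from lexical
(shared-term) similarity; a high-to-low scan is available by flag. Counting
**pair similarities** per bin (rather than patterns) is likewise the
package's reading of the heuristic — the histogram is over the similarity
distribution that θ thresholds. Two degenerate inputs are handled
explicitly: a single off-diagonal value is returned as θ directly, and an
all-equal similarity multiset raises `DegenerateHistogramError` carrying a
median-similarity fallback that the pipeline applies automatically.

## Lexicon induction

Within each cluster, occurrences of verb-tagged lemmas are counted across
the cluster's member pattern *types*; a verb reaching count ≥ 2 in at
least one cluster is selected. Counting types rather than corpus-frequency-
weighted occurrences means a verb must be corroborated by distinct
contexts that the kernel judged similar — a verb that always recurs in one
stereotyped context yields a single pattern type and is not selected. This
is what separates interaction verbs (which vary their modifiers) from
boilerplate verbs on synthetic corpora, and it is the package's
operationalization of "recurring within a cluster".

Normalization uses suffix rules (-s/-es/-ies/-ed/-ing with
consonant-doubling and final-e restoration) plus an irregular-form table
(~60 entries: *bound* → *bind*, etc.); nominalization uses suffix rules
(-ate → -ation, -ize → -ization, -act → -action, …) plus an irregular
table (*induce* → *induction*, *bind* → *binding*, …). Both tables are
small curated stand-ins for a full morphological lexicon, adequate for the
verb inventory of molecular-biology prose; unknown coinages normalize to
themselves and nominalize to the empty set. POS tags are taken from the
input corpus (the package runs no tagger).

## Dependency rules

Dependency distance is the link count of the shortest undirected path in
the dependency tree (networkx shortest path; a breadth-first oracle checks
the metric properties in tests). Only basic trees are accepted — multiple
heads or cycles are load-time errors — because a path-based distance
presumes tree structure. The artificial root is excluded from the
undirected view so distances never route through it.

RD1 emits one candidate per (entity pair, lexicon word) with both
distances ≤ 4 (the bound is the documented default, configurable). The
entity's anchor node is the **last** token of its span, reflecting the
head-final tendency of English noun phrases. The interaction word may be
any token matching the lexicon by lemma (surface fallback) that is not
itself inside an entity mention; it is not required to lie on the
entity-to-entity path — the distance-only reading reproduces the
six-candidate worked example. RD2 removes candidates whose interaction
word is verb-tagged and not strictly between the mentions' spans in
surface order; noun interaction words (e.g. *binding*) pass
unconditionally, as prenominal nominalizations legitimately precede both
entities. Disconnected graphs give infinite distance and RD1 simply fails
silently. Duplicate relations for one pair keep the lowest-total-distance
evidence.

## Constituency rules

RP1 searches every internal node for sibling NP/VP children (NP preceding
VP, matching canonical clause order; the constraint can be switched off)
such that the NP subtree dominates one entity's **full** span and the VP
subtree the other's, at any depth. Either entity may fill the NP role; the
emitted pair is unordered. RP2 accepts a structure if any leaf of the VP
subtree (outside entity spans) matches the lexicon; the any-leaf reading
is the package's choice over a stricter c-command requirement. One
relation is kept per (pair, word). In the combined pipeline the RP rules
run only on pairs the dependency rules did not extract; a flag enables
independent RP-only runs for ablations.

## Semi-supervised layer

Instances are entity pairs represented by the lemma sequence of the
shortest dependency path between their anchors, entity tokens masked as
`ENTITY` so names cannot be memorized. Similarity is
1 − Levenshtein/max-length on token sequences (unit costs). The KNN graph
links each node to its K = 5 most similar others (ties by index),
symmetrized. Labels propagate by clamped neighborhood averaging — scores
start at 1/0/0.5 for positive/negative/unlabeled, unlabeled scores are
replaced by their neighborhood mean until the maximum change is below
1e-6 — which converges because the update is an averaging contraction on a
graph with clamped boundary values; the fixed point equals the direct
linear-system solution, verified in tests. Score > 0.5 is positive; the
0.5 tie resolves to negative (conservative for precision). A hard-KNN
fallback (majority vote of labeled neighbors) is available by flag.

Rule correction ships in two modes because "correcting errors with rules"
is genuinely open: **override** (default) sets every rule-extracted
instance positive and never demotes; **fill_unknown** lets rules decide
only instances within a margin (default 0.05) of the tie point. The
labeled/unlabeled split is a seeded utility so runs are reproducible.

## Evaluation

Occurrence-level scoring: predictions and gold are sets of
(sentence id, unordered mention-id pair) keys, so each co-mention counts
separately. F = 2pr/(p+r) with 0 conventions when a denominator is empty.
Scores print ×100 at two decimals. Self-pairs (two mentions of the same
name) are excluded from pair enumeration by default, with a flag to
include them.

## Synthetic corpus

The generator emits template sentences *E1 ⟨verb⟩ E2* with deterministic
dependency trees and bracketings derived from the generating template —
this removes the external-parser dependency while preserving exactly the
structures the rules consume. Defaults: 200 sentences, 30-name entity
vocabulary, 60% of sentences built on one of six planted interaction verbs
(the remainder on six distractor verbs), and of the interaction sentences
10% negated (*does not V*) and 10% long-range (a 13-token prepositional
chain between the entities, which also pushes dependency distance to 7).
Interaction verbs take an adverbial modifier half the time (six shared
adverbs), giving each verb multiple pattern types; distractor verbs are
used in one stereotyped form each, the behavior that lets cluster-type
counting exclude them. Gold is every pair realized with an un-negated
interaction verb within the window.

What passing means — and does not. Negated and long-range sentences are
deliberately extracted by the rules (the rules carry no negation check,
and the NP+VP structure still holds at long range), so end-to-end
precision sits near 0.8, not 1.0: the tests exercise exactly the known
blind spots. The generator does not emulate parser noise, nested or
overlapping mentions, anaphora, or realistic lexical variety, so passing
recovery bounds here does not predict benchmark-corpus scores; the
ablation machinery accepts user-supplied parsed corpora for that. Problem
sizes in the test suite (200-sentence corpora, 5 generator seeds, 200
random clustering instances, 200-instance propagation sets) are chosen to
exercise every code path at desk scale.

## Worked-example fixtures

The two built-in analyzed sentences have dependency edges transcribed from
their printed shortest-path analyses; edges not implied by any printed
path attach determiners, conjuncts and modifiers minimally (each token one
head, tree-shaped, so all pairwise distances are forced). The p53
sentence's bracketing follows the sentence-level NP+VP analysis. These
fixtures pin the rule semantics: 6 RD1 candidates and 3 after RD2 on the
receptor sentence; an over-length dependency path but two NP+VP relations
on the p53 sentence.
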