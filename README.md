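# relmine

Unsupervised extraction of biomedical relations — protein–protein
interactions, gene–disease associations — from sentence-annotated text.

Most relation-extraction systems need labeled training data or a manually
compiled list of interaction words. `relmine` instead *induces* the
interaction vocabulary from unlabeled text and then applies two small sets
of syntactic rules, so the only inputs are sentences with entity mentions
and their parses.

## Method

**Interaction-word induction.** For every pair of entities co-mentioned
within a window (default 10 tokens), the token sequence between them is
kept as a candidate pattern after filtering stopwords, non-English tokens
and entity names; patterns containing a negation word (*no*, *not*,
*neither*) are pruned. Each pattern *p* is a term-frequency vector φ(p),
compared by the polynomial kernel

    K(p, q) = (⟨φ(p), φ(q)⟩ + c)^d        (defaults d = 2, c = 1)

Patterns are clustered greedily in descending frequency order: each pattern
joins the existing cluster with the highest average kernel similarity if
that average exceeds a threshold θ, else it starts a new cluster. θ is read
off the similarity histogram — the lower limit of the first interval whose
pair count collapses to ≤ 20% of the previous interval's. Verbs recurring
within a cluster become interaction verbs, normalized to citation form
(*activated* → *activate*) and extended to derived nouns
(*associate* → *association*).

**Rule-based extraction.** With dd(w₁, w₂) the number of links on the
shortest undirected path between two words in the dependency tree:

* **RD1** — both entities satisfy dd(entity, w) ≤ 4 for the same
  interaction word *w*;
* **RD2** — if *w* is a verb it must occur between the two entities in
  surface order;
* **RP1** — the entities are dominated by sibling NP and VP nodes under a
  common parent in the constituency tree;
* **RP2** — the VP subtree contains an interaction word.

The constituency rules run on the pairs the dependency rules miss, catching
long-range relations whose dependency paths exceed the bound. A
semi-supervised layer is available: entity-pair instances represented by
their shortest dependency path (entities masked) propagate a small labeled
seed set over a K-nearest-neighbor graph under edit similarity, and the
rule output then corrects the propagated labels.

Evaluation is occurrence-level ("one answer per occurrence"): every
(sentence, mention-pair) co-occurrence counts separately, scored by
precision, recall and F = 2pr/(p+r).

## Worked example

`examples/worked_example_rules.py` runs the rules on two built-in analyzed
sentences:

```
Recombinant neuregulin-2beta induces the tyrosine phosphorylation of ErbB2 , ErbB3 and ErbB4 ...
RD1 candidates (dd <= 4 to 'induces'): 6
RD2 keeps the pairs the verb lies between: 3
dependency distance induces <-> ErbB2: 3

A double point mutation in the activation domain of p53 impaired ... to interact with both TAFII40 and TAFII60 .
RD relations involving p53: none (path too long)
RP relation: (p53, TAFII40) via 'interact' in the VP
RP relation: (p53, TAFII60) via 'interact' in the VP
```

All six entity pairs of the receptor sentence are within dependency
distance 4 of *induces*, but only the three pairs the verb actually sits
between survive RD2 — these are the true interactions. In the p53 sentence
the p53→*interact* dependency path has 9 links, so the dependency rules
fail and the sentence-level NP+VP structure recovers both relations.

`examples/induce_lexicon.py` shows lexicon induction on a synthetic
200-sentence corpus:

```
clustering threshold theta=1.20, 12 clusters
induced verbs: ['activate', 'associate', 'bind', 'inhibit', 'interact', 'phosphorylate']
derived nouns: ['activation', 'association', 'binding', 'inhibition', 'interaction', 'phosphorylation']
planted-verb recall: 6/6, distractors admitted: []
```

The other examples (`end_to_end_extraction.py`, `semi_supervised_knn.py`)
run the full scored pipeline and the KNN hybrid.

A `relmine` console command exposes the same stages as file-to-file
subcommands (`simulate`, `extract-patterns`, `build-lexicon`, `extract`,
`semi`, `eval`, `ablate`); see `relmine --help`.

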