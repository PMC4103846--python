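"""Dependency and constituency rules on the two built-in worked examples.

The first sentence (neuregulin-2beta / ErbB receptors) shows the dependency
rules at work: RD1 admits every entity pair within dependency distance 4 of
the interaction verb, and RD2 then discards pairs the verb does not sit
between.  The second sentence (p53 / TAFII40 / TAFII60) has a dependency
path longer than the bound, so only the NP+VP constituency rules recover
its relations.
"""

from relmine import InteractionLexicon, apply_rd1, apply_rd2, dependency_distance
from relmine.phrase import apply_rp2, find_np_vp
from relmine.synthetic import worked_examples

erbb, p53 = worked_examples()

print(" ".join(t.surface for t in erbb.tokens))
lex = InteractionLexicon(verbs={"induce"})
rd1 = apply_rd1(erbb, lex, max_dd=4)
rd2 = apply_rd2(rd1, erbb)
print(f"RD1 candidates (dd <= 4 to 'induces'): {len(rd1)}")
for c in rd1:
    print(f"  ({c.pair.m1.id}, {c.pair.m2.id})  dd={c.dd1:.0f},{c.dd2:.0f}")
print(f"RD2 keeps the pairs the verb lies between: {len(rd2)}")
idx = next(t.index for t in erbb.tokens if t.surface == "induces")
print(f"dependency distance induces <-> ErbB2: "
      f"{dependency_distance(erbb.dependencies, idx, 8):.0f}\n")

print(" ".join(t.surface for t in p53.tokens))
lex = InteractionLexicon(verbs={"interact"})
rd = apply_rd2(apply_rd1(p53, lex), p53)
print(f"RD relations involving p53: "
      f"{[c.key for c in rd if 'p53' in c.key[1]] or 'none (path too long)'}")
for pair in p53.entity_pairs():
    for cand in apply_rp2(find_np_vp(p53.constituents, pair.m1, pair.m2), p53, lex):
        print(f"RP relation: ({cand.pair.m1.id}, {cand.pair.m2.id}) "
              f"via '{cand.word_lemma}' in the VP")
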