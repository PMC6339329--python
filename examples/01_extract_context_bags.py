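"""Turn a dependency-parsed sentence into (word, context) pairs and bags.

The parse of "an efficient modulator regulates cells" yields one pair per
retained arc: the head word is the target and the dependent, tagged with
the arc's canonical bag label, is its context.  Lexicalized labels collapse
(prep_in -> prep) and near-synonymous labels merge (dobj/iobj -> obj).
"""

from bioverb import (
    ExtractionConfig,
    ParsedSentence,
    ParsedToken,
    extract_pairs,
    group_into_bags,
)

rows = [
    (1, "an", "DET", 3, "det"),
    (2, "efficient", "ADJ", 3, "amod"),
    (3, "modulator", "NOUN", 4, "nsubj"),
    (4, "regulates", "VERB", 0, "root"),
    (5, "cells", "NOUN", 4, "dobj"),
    (6, "culture", "NOUN", 4, "prep_in"),
]
sentence = ParsedSentence(
    tokens=[
        ParsedToken(index=i, form=f, lemma=f, pos=p, head=h, deprel=d)
        for i, f, p, h, d in rows
    ]
)

pairs = extract_pairs(sentence, ExtractionConfig(inverse_contexts=False))
print("head-side pairs (word, context):")
for p in pairs:
    print(f"  ({p.word}, {p.context})   -> bag {p.bag!r}")

bags = group_into_bags(pairs)
print("\nbag sizes:", {label: bag.pair_count for label, bag in sorted(bags.items())})
print(
    "\nThe verb 'regulates' collects a subj, an obj and a prep context;"
    "\nnoun-side bags (det, amod) carry no verb information."
)
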