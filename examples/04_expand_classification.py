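"""Expand a seed verb classification by nearest-centroid assignment.

Splits the planted classes into seed members and held-out candidates,
represents each class by the centroid of its seed vectors, assigns every
candidate to the euclidean-nearest centroid, and prints the expanded
lexicon plus a review sheet (top dependency signatures with examples) for
one candidate.
"""

from bioverb import (
    SynthesisParams,
    TrainingConfig,
    assign,
    build_review_sheet,
    compute_centroids,
    expand_lexicon,
    extract_corpus_pairs,
    filter_pairs,
    generate,
    group_into_bags,
    split_lexicon,
    train_sgns,
)
from bioverb.synthetic import class_index_of

params = SynthesisParams(
    n_classes=4,
    verbs_per_class=6,
    noun_pool_per_class=6,
    n_sentences=8000,
    informative_bags=frozenset({"subj", "obj"}),
    signal_strength=0.95,
    seed=3,
)
sentences, truth = generate(params)
bags = group_into_bags(filter_pairs(extract_corpus_pairs(sentences), 50))
cfg = TrainingConfig(dim=25, negatives=5, epochs=5, min_count=50, seed=7)
vectors = train_sgns(bags["subj"].pairs + bags["obj"].pairs, cfg)

lexicon, candidates = split_lexicon(truth, seeds_per_class=3, seed=3)
centroids = compute_centroids(lexicon, vectors)
assignments, oov = assign(candidates, centroids, vectors)
expanded = expand_lexicon(lexicon, assignments)

correct = sum(a.class_index == class_index_of(truth, a.verb) for a in assignments)
print(f"{len(assignments)} candidates assigned ({len(oov)} out of vocabulary)")
print(f"{correct}/{len(assignments)} returned to their true planted class")
print(f"expanded lexicon: {expanded.n_verbs} verbs in {expanded.n_classes} classes\n")
for idx in sorted(expanded.classes):
    cls = expanded.classes[idx]
    print(f"  {idx} {cls.name}: seeds={cls.members} candidates={cls.candidates}")

verb = assignments[0].verb
sheet = build_review_sheet(verb, sentences)
print(f"\nreview sheet for {verb!r} — top context signatures:")
for sig, freq in sheet.top_contexts[:5]:
    print(f"  {sig:18s} {freq:5d}   e.g. {sheet.examples[sig][0]!r}")
print(
    "\nSignatures like subj#obj summarize which dependents the verb governs"
    "\nper sentence; experts use them to judge syntactic fit of candidates."
)
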