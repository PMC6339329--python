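"""Find the verb-specific context configuration by filtered beam descent.

Bags whose singleton model scores rho < 0.2 are dropped (here: the noun-side
noise bags, which contain no verbs at all); the beam then descends from the
full surviving configuration, removing one bag at a time and keeping only
strictly improving children.  On this corpus the subject and object pools
carry complementary class information, so the best configuration is their
union rather than any singleton.
"""

from bioverb import (
    SynthesisParams,
    TrainingConfig,
    derive_gold,
    extract_corpus_pairs,
    filter_pairs,
    generate,
    group_into_bags,
    run_search,
)

params = SynthesisParams(
    n_sentences=20_000,
    informative_bags=frozenset({"subj", "obj"}),
    signal_strength=0.95,
    seed=1,
)
sentences, truth = generate(params)
bags = group_into_bags(filter_pairs(extract_corpus_pairs(sentences), 100))
gold = derive_gold(truth, 300, seed=1)

cfg = TrainingConfig(dim=50, negatives=5, epochs=5, min_count=100, seed=7)
trace, vectors = run_search(bags, gold, cfg, threshold=0.2)

print(f"{trace.n_visited} of {trace.total_possible} configurations visited:")
for s in trace.visited:
    print(f"  level {s.level}: {'+'.join(sorted(s.bags)):24s} rho={s.score:.4f}")
print(f"\nbaselines: { {k: round(v, 4) for k, v in trace.baselines.items()} }")
best = trace.best
print(f"best configuration: {'+'.join(sorted(best.bags))} (rho={best.score:.4f})")
print(
    "\nScore -1.0 marks bags with no verb coverage (noise bags); the"
    "\nsearch recovers exactly the planted informative relations."
)
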