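# Methods

This note documents the models, defaults and design choices behind
`bioverb`, and what its tests do and do not demonstrate.

## Context extraction

Each dependency arc (head *h*, dependent *d*, label ℓ) becomes the pair
`(norm(h), norm(d) + "_" + bag(ℓ))`, where `bag` is collapse (`prep_*`,
`nmod*` → `prep`; `conj_*` → `conj`) followed by a merge table folding the
bottom levels of the Stanford-typed hierarchy into canonical bags
(`dobj`/`iobj`/`dative` → `obj`; `nsubj`/`nsubjpass`/`csubj`/`csubjpass` →
`subj`; `xcomp`/`ccomp`/`acomp` → `comp`; `rcmod`/`relcl` → `rel`;
`pobj` → `prep`; `pcomp` stays). The full merge inventory beyond the
canonical examples is not standardized anywhere, so the table is a declared,
overridable config artifact rather than a hard-coded truth.

Decisions taken where practice varies:

- **Word normalization** — lemma when the parse provides one, else the
  lowercased surface form. Verb lexicons cite lemmas; normalization keeps
  inflected tokens from fragmenting the vocabulary.
- **Inverse contexts** — ON by default with the `-1` suffix (the dependent
  also receives the head as context, e.g. `(efficient, modulator_amod-1)`),
  the convention of dependency-embedding tooling; switchable off.
- **Drop set** — `{punct, dep, root}`. Punctuation is uninformative;
  `dep` is the parser's "unknown" label; `root` has no lexical head.
- **Frequency boundary** — "fewer than 100" is a strict `< 100` removal: a
  word at exactly 100 occurrences is kept. A separate pair-multiplicity
  floor exists for rare-pair pruning and defaults to 1 (off).

Invariants tested: bag sizes partition the retained arcs; label
normalization is idempotent; pair files round-trip byte-identically.

## SGNS training

Two matrices (word and context vectors); for each positive pair, `negatives`
noise contexts drawn from the context unigram distribution raised to 0.75.
Plain SGD, learning rate decaying linearly from 0.025 to 2.5e-6 over
`epochs × n_pairs` updates; word vectors initialized uniform in
±0.5/dim, context vectors at zero; sigmoid via a 2048-entry lookup table
clipped at ±8 — all standard word2vec numerics. The inner loop is
numba-compiled with an inline xorshift64* PRNG, single-threaded, in fixed
pair order: a fixed seed yields bit-identical vectors on a given platform,
which the determinism tests rely on.

Defaults: `dim=300`, `negatives=15`, `epochs=5`, `min_count=100` (words and
contexts pruned independently), `subsample_threshold=0` (off — the corpora
the package trains on at test scale have no stop-word-like mass to discard).
Synthetic-scale runs use `dim=50, negatives=5, min_count=100` on ~20 000
sentences — large enough that planted structure is recoverable, small
enough that a full configuration search trains its ~10 models in seconds.

The bag-of-words baseline reuses the same trainer on pairs enumerated from
symmetric windows (default width 5), so "BOW vs dependency contexts" is a
pure contexts comparison, not a trainer comparison.

## Similarity evaluation

Model score for a gold verb pair = cosine of the two vectors; quality =
Spearman ρ between model scores and human scores, computed as the Pearson
correlation of average-ties ranks (equals the rank-difference formula when
ties are absent; verified against an independent implementation to 1e-12).
Out-of-vocabulary pairs are skipped and reported as coverage, never imputed
— imputing would reward low-coverage models. Fewer than two scored pairs is
an error rather than a meaningless ρ; the search stage maps that error to a
score of −1.0, which is how verb-free noise bags (e.g. `amod`) are
eliminated at the singleton-filter stage.

## Configuration search

Singleton filter at ρ ≥ 0.2 (inclusive, as the threshold is conventionally
stated), then beam descent: from the full M-set, score every child with one
bag removed; a child enters the next frontier only if it **strictly**
outperforms its parent (ties do not advance — prevents plateau wandering);
stop at singletons or an empty frontier. All frontier members expand (no
width cap); a global memo guarantees no configuration is trained twice, and
the singleton scores from the filter stage pre-seed the memo. One shared
training seed across configurations makes score differences attributable to
the contexts rather than sampling noise.

On monotone landscapes (dropping any noise bag strictly helps, dropping any
signal bag strictly hurts) the descent provably reaches the pure-signal
configuration, and the tests verify equality with exhaustive enumeration
for every signal/noise split with M ≤ 5. On non-monotone landscapes the
descent is a heuristic and can miss the global optimum — that is the price
of visiting ~M² rather than 2^M configurations.

## Nearest-centroid classification

Centroid = arithmetic mean of in-vocabulary member vectors (OOV members
skipped with a warning; a fully OOV class is an error). Assignment =
euclidean-nearest centroid on **raw** vectors — cosine/normalized distance
is available behind a flag but off, since the method is defined in terms of
euclidean distance; ties break to the lexicographically smallest class
index; hard single-class assignment only. OOV candidates are reported
separately, never force-assigned. Assignments are verified against a
brute-force all-pairs distance scan on random instances.

Review materials: a sentence's signature is the `#`-joined *set* (duplicates
collapsed — two `prep` dependents count once) of the verb's dependent bag
labels, ordered subj, obj, comp, pcomp, prep, conj, rel; per verb the top-10
signatures by frequency are kept (ties by first corpus occurrence) with up
to 3 example sentences each, first occurrences in corpus order, hence a
deterministic ≤ 30-sentence packet.

## Validation summaries

Per class: `100·n_correct/n_candidates`. Group totals report both macro
(unweighted mean of per-class percentages, computed with compensated
summation so record order cannot perturb the value) and micro (pooled
counts). Macro is the headline figure because that is how such
expert-validation tables are conventionally totalled; micro is emitted
alongside for transparency, and the two are deliberately not reconciled.
Rounding is half-up to one decimal, at report time only.

## Synthetic corpus generator

Each sentence is one root verb with: a subject (always; `nsubj` 80% /
`nsubjpass` 20%), an object (p=0.85; `dobj` 85% / `iobj` 15%), and a
prepositional dependent (p=0.6; `prep_in/of/with/by`) — exercising the
collapse and merge paths — plus class-independent noise on the nouns
(determiners p=0.5, adjectives p=0.4, noun compounds p=0.25). Dependents of
*informative* relations come from a class noun pool with probability
`signal_strength`, else from a shared global pool; noise relations never see
class pools.

**Complementary pools.** With two or more informative relations, each
relation's pools are shared by a *group* of classes: the first relation
indexes the class's row and the others its column in a ⌈√C⌉-grid, so the
(row, column) pair — but neither relation alone — identifies the class.
This is deliberate: were every class's pools fully private, any single
informative bag would saturate the similarity gold standard's ceiling and
the configuration search would have no reason to prefer the union over a
singleton, making "the best configuration combines the informative
relations" an unfalsifiable coin-flip instead of a testable property. With
a single informative relation the pools are fully class-private.

Defaults (6 classes × 8 verbs, 8-noun pools per class-group, 40 shared
nouns, 20 000 sentences, signal 0.95) give every retained word a corpus
frequency comfortably above the 100-count filter while keeping a full
search-plus-classification run in single-digit seconds. The derived gold
table scores same-class pairs at a high anchor and cross-class pairs at a
low anchor with Gaussian jitter (sd 0.05) so ranks are informative;
seed/candidate splits hold out verbs per class uniformly at random.

What the generator does *not* emulate: multi-verb sentences, parser errors,
polysemy, Zipfian vocabularies, or any semantic content in the noise
relations. Passing recovery tests therefore shows the pipeline's machinery
is sound under its own assumptions, not that the learned configurations or
classes transfer to real parsed literature.

## Scale and determinism of the checked results

The acceptance checks run the full pipeline at dim 50 on ~20 000-sentence
corpora (3 seeds for recovery, plus a zero-signal null verified at chance
level by a one-sided binomial test at α = 0.01). Combinatorial, validation
and lexicon accounting are exact. Full determinism — byte-identical pair
files, vector files, search traces and lexicons across repeated runs with
one seed — is asserted end to end; it holds per platform (floating-point
ordering is fixed, but bit-identity across different CPU/compiler stacks is
not claimed).

## Known limitations

- Beam descent is heuristic off the monotone regime (above).
- Absolute ρ values from full-scale corpora depend on corpus and unstated
  training hyperparameters and are not reproducible here; only behavioural
  properties are claimed.
- The trainer is CPU-bound pure SGD; it is meant for corpora up to the
  low millions of pairs, not billions.
- Subword/character information (productive biomedical morphology like
  *phosphorylate/dephosphorylate*) is out of scope.
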