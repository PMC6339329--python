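import numpy as np
import pytest

from bioverb.conll import read_parsed_corpus, write_conll
from bioverb.contexts import extract_corpus_pairs, group_into_bags
from bioverb.synthetic import (
    SynthesisParams,
    class_index_of,
    derive_gold,
    generate,
    split_lexicon,
    write_dataset,
)

TINY = SynthesisParams(
    n_classes=3,
    verbs_per_class=4,
    noun_pool_per_class=4,
    n_sentences=300,
    informative_bags=frozenset({"subj", "obj"}),
    seed=9,
)


def test_params_validation():
    with pytest.raises(ValueError, match="signal_strength"):
        SynthesisParams(signal_strength=1.5)
    with pytest.raises(ValueError, match="disjoint"):
        SynthesisParams(
            informative_bags=frozenset({"subj"}), noise_bags=frozenset({"subj"})
        )


def test_generated_corpus_is_valid_conll(tmp_path):
    sentences, _ = generate(TINY)
    assert len(sentences) == 300
    path = tmp_path / "c.conllu"
    write_conll(sentences, path)
    reread = list(read_parsed_corpus(path))
    assert len(reread) == 300
    assert all(any(t.head == 0 for t in s.tokens) for s in reread)


def test_one_root_verb_per_sentence():
    sentences, truth = generate(TINY)
    for sent in sentences:
        roots = [t for t in sent.tokens if t.head == 0]
        assert len(roots) == 1
        assert roots[0].norm in truth.verb_to_class


def test_generation_reproducible_under_seed():
    s1, _ = generate(TINY)
    s2, _ = generate(TINY)
    assert s1 == s2


def test_full_signal_keeps_dependents_in_class_pool():
    params = SynthesisParams(
        n_classes=3,
        verbs_per_class=3,
        noun_pool_per_class=4,
        n_sentences=400,
        informative_bags=frozenset({"subj", "obj"}),
        signal_strength=1.0,
        seed=2,
    )
    sentences, truth = generate(params)
    for sent in sentences:
        for head, dep, deprel in sent.arcs():
            if head.norm in truth.verb_to_class and deprel.startswith(
                ("nsubj", "dobj", "iobj")
            ):
                pool = truth.class_pools[truth.verb_to_class[head.norm]]
                assert dep.norm in pool


def test_zero_signal_never_uses_class_pools():
    params = SynthesisParams(
        n_classes=3,
        verbs_per_class=3,
        noun_pool_per_class=4,
        n_sentences=400,
        informative_bags=frozenset({"subj", "obj"}),
        signal_strength=0.0,
        seed=2,
    )
    sentences, truth = generate(params)
    pooled = {n for pool in truth.class_pools.values() for n in pool}
    for sent in sentences:
        for _, dep, _ in sent.arcs():
            assert dep.norm not in pooled


def test_noise_bags_attach_to_nouns_only():
    sentences, truth = generate(TINY)
    pairs = extract_corpus_pairs(sentences)
    bags = group_into_bags(pairs)
    verbs = set(truth.verb_to_class)
    for label in ("amod", "det", "nn"):
        heads = {p.word for p in bags[label].pairs if not p.context.endswith("-1")}
        assert not heads & verbs


def test_derive_gold_same_class_scores_higher():
    _, truth = generate(TINY)
    pairs = derive_gold(truth, 40, seed=1, jitter=0.0)
    for p in pairs:
        same = truth.verb_to_class[p.verb1] == truth.verb_to_class[p.verb2]
        assert p.human_score == (1.0 if same else 0.0)


def test_derive_gold_sizes_and_errors():
    _, truth = generate(TINY)
    assert derive_gold(truth, 0, seed=1) == []
    n_verbs = len(truth.verb_to_class)
    too_many = n_verbs * (n_verbs - 1) // 2 + 1
    with pytest.raises(ValueError, match="exceeds"):
        derive_gold(truth, too_many, seed=1)


def test_split_lexicon_counts_and_reproducibility():
    _, truth = generate(TINY)
    lex, cands = split_lexicon(truth, seeds_per_class=2, seed=5)
    assert all(len(c.members) == 2 for c in lex.classes.values())
    assert len(cands) == 3 * (4 - 2)
    assert not set(cands) & lex.all_seed_verbs()
    lex2, cands2 = split_lexicon(truth, seeds_per_class=2, seed=5)
    assert cands == cands2
    assert {k: v.members for k, v in lex.classes.items()} == {
        k: v.members for k, v in lex2.classes.items()
    }
    for v in cands:
        assert class_index_of(truth, v) in lex.classes


def test_split_lexicon_infeasible_errors():
    _, truth = generate(TINY)
    with pytest.raises(ValueError, match="candidates"):
        split_lexicon(truth, seeds_per_class=4, seed=1)
    with pytest.raises(ValueError, match=">= 1"):
        split_lexicon(truth, seeds_per_class=0, seed=1)


def test_write_dataset_bundle(tmp_path):
    paths = write_dataset(TINY, tmp_path / "sim", n_gold_pairs=30, seeds_per_class=2)
    for path in paths.values():
        assert path.exists()
    from bioverb.similarity import load_gold

    assert len(load_gold(paths["gold"])) == 30
    assert len(list(read_parsed_corpus(paths["corpus"]))) == 300
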