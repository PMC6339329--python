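import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioverb.contexts import (
    CANONICAL_BAGS,
    DEFAULT_MERGE_TABLE,
    ExtractionConfig,
    WordContextPair,
    canonical_bag,
    collapse_label,
    extract_pairs,
    filter_pairs,
    group_into_bags,
    merge_label,
    read_pairs,
    write_pairs,
)

from conftest import make_sentence


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("prep_in", "prep"),
        ("prep_of", "prep"),
        ("conj_or", "conj"),
        ("conj_and", "conj"),
        ("amod", "amod"),
        ("nsubj", "nsubj"),
    ],
)
def test_collapse_label(raw, expected):
    assert collapse_label(raw) == expected


@pytest.mark.parametrize(
    "collapsed, expected",
    [
        ("dobj", "obj"),
        ("iobj", "obj"),
        ("nsubj", "subj"),
        ("nsubjpass", "subj"),
        ("xcomp", "comp"),
        ("rcmod", "rel"),
        ("pcomp", "pcomp"),
        ("amod", "amod"),  # not in the table: passes through
    ],
)
def test_merge_label(collapsed, expected):
    assert merge_label(collapsed) == expected


def test_seven_canonical_bags_producible():
    """The merge table can produce every canonical verb-related bag."""
    produced = set(DEFAULT_MERGE_TABLE.values()) | {"prep", "conj"}
    assert set(CANONICAL_BAGS) <= produced


@given(st.sampled_from(sorted(DEFAULT_MERGE_TABLE) + ["prep_in", "conj_or", "amod", "foo"]))
@settings(max_examples=30, derandomize=True)
def test_label_normalization_idempotent(label):
    once = canonical_bag(label)
    assert canonical_bag(once) == once


def test_extract_head_side_pair(modulator_sentence):
    pairs = extract_pairs(
        modulator_sentence, ExtractionConfig(inverse_contexts=False)
    )
    by = {(p.word, p.context) for p in pairs}
    assert ("modulator", "efficient_amod") in by
    assert ("regulates", "cells_obj") in by
    assert ("regulates", "modulator_subj") in by


def test_extract_inverse_pairs(modulator_sentence):
    pairs = extract_pairs(modulator_sentence, ExtractionConfig(inverse_contexts=True))
    by = {(p.word, p.context) for p in pairs}
    assert ("efficient", "modulator_amod-1") in by
    assert ("cells", "regulates_obj-1") in by
    # every arc yields exactly two pairs
    assert len(pairs) == 2 * len(
        extract_pairs(modulator_sentence, ExtractionConfig(inverse_contexts=False))
    )


def test_punct_and_drop_set_arcs_emit_nothing():
    sent = make_sentence(
        [("go", "VERB", 0, "root"), (".", "PUNCT", 1, "punct"), ("x", "X", 1, "dep")]
    )
    assert extract_pairs(sent) == []


def test_filter_pairs_strict_less_than_boundary():
    pairs = [WordContextPair("w", "c_obj", "obj")] * 100 + [
        WordContextPair("rare", "c_obj", "obj")
    ] * 99
    kept = filter_pairs(pairs, min_word_count=100)
    assert {p.word for p in kept} == {"w"}
    assert len(kept) == 100


def test_filter_pairs_threshold_zero_is_identity():
    pairs = [WordContextPair("a", "b_obj", "obj")]
    assert filter_pairs(pairs, min_word_count=0) == pairs


def test_filter_pairs_pair_floor():
    pairs = [WordContextPair("w", "c1_obj", "obj")] * 3 + [
        WordContextPair("w", "c2_obj", "obj")
    ]
    kept = filter_pairs(pairs, min_word_count=0, min_pair_count=2)
    assert {p.context for p in kept} == {"c1_obj"}


def test_group_into_bags_partition():
    pairs = [
        WordContextPair("regulate", "cells_obj", "obj"),
        WordContextPair("fire", "neuron_obj", "obj"),
        WordContextPair("bind", "protein_subj", "subj"),
    ]
    bags = group_into_bags(pairs)
    assert bags["obj"].pair_count == 2
    assert sum(b.pair_count for b in bags.values()) == len(pairs)
    assert group_into_bags([]) == {}


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["a", "b", "c"]),
            st.sampled_from(["x", "y"]),
            st.sampled_from(["obj", "subj", "amod"]),
        ),
        max_size=50,
    )
)
@settings(max_examples=25, derandomize=True)
def test_partition_property(triples):
    pairs = [WordContextPair(w, f"{c}_{l}", l) for w, c, l in triples]
    bags = group_into_bags(pairs)
    assert sum(b.pair_count for b in bags.values()) == len(pairs)
    for label, bag in bags.items():
        assert all(p.bag == label for p in bag.pairs)


def test_pair_file_roundtrip_and_determinism(tmp_path, modulator_sentence):
    pairs = extract_pairs(modulator_sentence)
    p1, p2 = tmp_path / "a.pairs", tmp_path / "b.pairs"
    write_pairs(pairs, p1)
    write_pairs(extract_pairs(modulator_sentence), p2)
    assert p1.read_bytes() == p2.read_bytes()  # byte-identical across runs
    assert read_pairs(p1) == pairs
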