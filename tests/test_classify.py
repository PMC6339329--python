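import numpy as np
import pytest

from bioverb.classify import (
    SeedLexicon,
    VerbClass,
    assign,
    build_review_sheet,
    compute_centroids,
    context_signature,
    expand_lexicon,
)
from bioverb.embeddings import WordVectorSet

from conftest import make_sentence


def vecset(mapping):
    words = sorted(mapping)
    return WordVectorSet(words, np.array([mapping[w] for w in words], dtype=float))


def test_centroid_is_arithmetic_mean():
    lex = SeedLexicon({"1.0.0": VerbClass("c", ["a", "b"])})
    vecs = vecset({"a": [0.0, 0.0], "b": [2.0, 0.0]})
    cents = compute_centroids(lex, vecs)
    np.testing.assert_array_equal(cents["1.0.0"].vector, [1.0, 0.0])
    assert cents["1.0.0"].n_members_used == 2


def test_centroid_single_member_and_oov_skip():
    lex = SeedLexicon(
        {"1.0.0": VerbClass("c", ["a"]), "2.0.0": VerbClass("d", ["b", "ghost"])}
    )
    vecs = vecset({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    with pytest.warns(UserWarning, match="ghost"):
        cents = compute_centroids(lex, vecs)
    np.testing.assert_array_equal(cents["1.0.0"].vector, [1.0, 2.0])
    np.testing.assert_array_equal(cents["2.0.0"].vector, [3.0, 4.0])
    assert cents["2.0.0"].n_members_used == 1


def test_centroid_all_oov_class_errors():
    lex = SeedLexicon({"1.0.0": VerbClass("c", ["ghost"])})
    with pytest.raises(ValueError, match="1.0.0"):
        compute_centroids(lex, vecset({"a": [1.0]}))


def test_assign_nearest_and_margin():
    lex = SeedLexicon(
        {"A": VerbClass("a", ["pa"]), "B": VerbClass("b", ["pb"])}
    )
    vecs = vecset({"pa": [1.0, 0.0], "pb": [11.0, 0.0], "cand": [4.0, 0.0]})
    cents = compute_centroids(lex, vecs)
    assignments, oov = assign(["cand", "missing"], cents, vecs)
    assert oov == ["missing"]
    (a,) = assignments
    assert a.class_index == "A"
    assert a.distance == pytest.approx(3.0)
    assert a.runner_up_index == "B"
    assert a.margin == pytest.approx(4.0)


def test_assign_identical_to_sole_seed():
    lex = SeedLexicon({"C": VerbClass("c", ["s"]), "D": VerbClass("d", ["t"])})
    vecs = vecset({"s": [5.0, 5.0], "t": [-5.0, 0.0], "cand": [5.0, 5.0]})
    assignments, _ = assign(["cand"], compute_centroids(lex, vecs), vecs)
    assert assignments[0].class_index == "C"
    assert assignments[0].distance == 0.0


def test_assign_tie_breaks_to_smallest_class_index():
    lex = SeedLexicon({"2.0": VerbClass("x", ["p"]), "1.9": VerbClass("y", ["q"])})
    vecs = vecset({"p": [1.0, 0.0], "q": [-1.0, 0.0], "cand": [0.0, 0.0]})
    assignments, _ = assign(["cand"], compute_centroids(lex, vecs), vecs)
    assert assignments[0].class_index == "1.9"
    assert assignments[0].margin == 0.0


def test_assign_matches_bruteforce_scan():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n_classes, n_cands, dim = 5, 20, 10
        cents_m = rng.normal(size=(n_classes, dim))
        cand_m = rng.normal(size=(n_cands, dim))
        names = [f"{i}.0" for i in range(n_classes)]
        lex = SeedLexicon(
            {names[i]: VerbClass(f"c{i}", [f"seed{i}"]) for i in range(n_classes)}
        )
        mapping = {f"seed{i}": cents_m[i] for i in range(n_classes)}
        mapping.update({f"cand{j}": cand_m[j] for j in range(n_cands)})
        vecs = vecset(mapping)
        cents = compute_centroids(lex, vecs)
        assignments, _ = assign([f"cand{j}" for j in range(n_cands)], cents, vecs)
        for j, a in enumerate(assignments):
            dists = {
                name: float(np.linalg.norm(cents[name].vector - cand_m[j]))
                for name in names
            }
            best = min(sorted(dists), key=dists.get)
            assert a.class_index == best
            assert a.distance == pytest.approx(dists[best])


def test_assign_invariant_under_candidate_order():
    rng = np.random.default_rng(5)
    lex = SeedLexicon({f"{i}.0": VerbClass(f"c{i}", [f"s{i}"]) for i in range(4)})
    mapping = {f"s{i}": rng.normal(size=6) for i in range(4)}
    mapping.update({f"v{j}": rng.normal(size=6) for j in range(12)})
    vecs = vecset(mapping)
    cents = compute_centroids(lex, vecs)
    cands = [f"v{j}" for j in range(12)]
    forward, _ = assign(cands, cents, vecs)
    backward, _ = assign(cands[::-1], cents, vecs)
    assert {a.verb: a.class_index for a in forward} == {
        a.verb: a.class_index for a in backward
    }


def _lexicon_192_over_50():
    """A 50-class seed lexicon holding 192 verbs (like the published seed)."""
    classes = {}
    verb = 0
    for i in range(50):
        size = 4 if i < 42 else 3  # 42*4 + 8*3 = 192
        classes[f"{i + 1}.0.0"] = VerbClass(
            f"class{i}", [f"seed{verb + j}" for j in range(size)]
        )
        verb += size
    lex = SeedLexicon(classes)
    assert lex.n_verbs == 192
    return lex


def test_expand_lexicon_192_plus_957_gives_1149():
    from bioverb.classify import Assignment

    lex = _lexicon_192_over_50()
    assignments = [
        Assignment(f"cand{j}", f"{(j % 50) + 1}.0.0", 1.0, None, 0.5)
        for j in range(957)
    ]
    expanded = expand_lexicon(lex, assignments)
    assert expanded.n_verbs == 1149
    assert expanded.n_classes == 50
    assert lex.n_verbs == 192  # original untouched


def test_expand_lexicon_empty_assignments_is_identity():
    lex = _lexicon_192_over_50()
    assert expand_lexicon(lex, []).n_verbs == lex.n_verbs


def test_expand_lexicon_drops_duplicate_with_warning():
    from bioverb.classify import Assignment

    lex = SeedLexicon({"1.0": VerbClass("c", ["keep"])})
    with pytest.warns(UserWarning, match="keep"):
        expanded = expand_lexicon(lex, [Assignment("keep", "1.0", 0.1, None, 0.0)])
    assert expanded.n_verbs == 1


def test_expand_lexicon_unknown_class_errors():
    from bioverb.classify import Assignment

    lex = SeedLexicon({"1.0": VerbClass("c", ["a"])})
    with pytest.raises(ValueError, match="9.9"):
        expand_lexicon(lex, [Assignment("b", "9.9", 0.1, None, 0.0)])


def test_lexicon_tsv_roundtrip(tmp_path):
    lex = SeedLexicon(
        {
            "1.2": VerbClass("affect", ["modulate", "regulate"], ["impact"]),
            "2.2.1": VerbClass("modification", ["phosphorylate"]),
        }
    )
    path = tmp_path / "lex.tsv"
    lex.save_tsv(path)
    again = SeedLexicon.load_tsv(path)
    assert again.classes["1.2"].members == ["modulate", "regulate"]
    assert again.classes["1.2"].candidates == ["impact"]
    assert again.classes["2.2.1"].members == ["phosphorylate"]


# --- review materials ------------------------------------------------------

def regulate_sentence(with_obj=True, with_prep=False, sent_id="s"):
    rows = [("dox", "NOUN", 2 if not with_obj else 2, "nsubj")]
    rows = [("dox", "NOUN", 2, "nsubj"), ("regulate", "VERB", 0, "root")]
    if with_obj:
        rows.append(("expression", "NOUN", 2, "dobj"))
    if with_prep:
        rows.append(("cells", "NOUN", 2, "prep_in"))
    return make_sentence(rows, sent_id=sent_id)


def test_signature_subj_obj():
    sigs = context_signature("regulate", [regulate_sentence()])
    assert sigs == [("subj#obj", 1)]


def test_signature_single_subj():
    sigs = context_signature("regulate", [regulate_sentence(with_obj=False)])
    assert sigs == [("subj", 1)]


def test_signature_canonical_order_and_duplicate_collapse():
    sent = make_sentence(
        [
            ("a", "NOUN", 2, "nsubj"),
            ("regulate", "VERB", 0, "root"),
            ("b", "NOUN", 2, "prep_in"),
            ("c", "NOUN", 2, "prep_of"),  # second prep collapses
            ("d", "NOUN", 2, "dobj"),
        ]
    )
    assert context_signature("regulate", [sent]) == [("subj#obj#prep", 1)]


def test_signature_top10_truncation():
    corpus = []
    # 12 distinct signatures with frequencies 13, 12, ..., 2
    labels = ["nsubj", "dobj", "prep_in", "xcomp", "conj_and", "rcmod"]
    from itertools import combinations

    sig_variants = list(combinations(labels, 2))[:12]
    for rank, combo in enumerate(sig_variants):
        for _ in range(13 - rank):
            rows = [("regulate", "VERB", 0, "root")] + [
                (f"w{i}", "NOUN", 1, lab) for i, lab in enumerate(combo)
            ]
            corpus.append(make_sentence(rows))
    sigs = context_signature("regulate", corpus)
    assert len(sigs) == 10
    assert [f for _, f in sigs] == list(range(13, 3, -1))  # 2 rarest dropped


def test_signature_absent_verb_empty():
    assert context_signature("missing", [regulate_sentence()]) == []


def test_review_sheet_three_per_signature():
    corpus = [regulate_sentence(sent_id=f"a{i}") for i in range(5)] + [
        regulate_sentence(with_obj=False, sent_id=f"b{i}") for i in range(2)
    ]
    sheet = build_review_sheet("regulate", corpus)
    assert sheet.examples["subj#obj"] == ["dox regulate expression"] * 3
    assert len(sheet.examples["subj"]) == 2  # supply-limited
    assert sheet.n_sentences == 5


def test_review_sheet_absent_verb_empty():
    sheet = build_review_sheet("missing", [regulate_sentence()])
    assert sheet.top_contexts == []
    assert sheet.n_sentences == 0


def test_review_sheet_full_packet_is_thirty(small_planted):
    """With >= 10 signatures at >= 3 occurrences the packet holds 30 sentences."""
    params, sentences, truth = small_planted
    verb = sorted(truth.verb_to_class)[0]
    sheet = build_review_sheet(verb, sentences)
    assert len(sheet.top_contexts) <= 10
    assert sheet.n_sentences <= 3 * len(sheet.top_contexts)
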