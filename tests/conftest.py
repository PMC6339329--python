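from __future__ import annotations

import pytest

from bioverb.conll import ParsedSentence, ParsedToken


def make_sentence(rows, sent_id="s1"):
    """rows: (form, pos, head, deprel) tuples; lemma defaults to the form."""
    tokens = [
        ParsedToken(
            index=i + 1, form=form, lemma=form, pos=pos, head=head, deprel=deprel
        )
        for i, (form, pos, head, deprel) in enumerate(rows)
    ]
    sent = ParsedSentence(tokens=tokens, sent_id=sent_id)
    sent.validate()
    return sent


@pytest.fixture
def modulator_sentence():
    # "an efficient modulator regulates cells" — head-indexed parse
    return make_sentence(
        [
            ("an", "DET", 3, "det"),
            ("efficient", "ADJ", 3, "amod"),
            ("modulator", "NOUN", 4, "nsubj"),
            ("regulates", "VERB", 0, "root"),
            ("cells", "NOUN", 4, "dobj"),
        ]
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small planted corpus shared by the slower structural tests."""
    from bioverb.synthetic import SynthesisParams, generate

    params = SynthesisParams(
        n_classes=4,
        verbs_per_class=6,
        noun_pool_per_class=6,
        n_sentences=6000,
        informative_bags=frozenset({"subj", "obj"}),
        signal_strength=0.95,
        seed=42,
    )
    return params, *generate(params)
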