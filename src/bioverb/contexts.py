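"""Building dependency context bags from parsed sentences.

Every dependency arc (head, dependent, label) becomes a ``(word, context)``
pair such as ``(modulator, efficient_amod)``: the head is the target word and
the dependent, suffixed with the arc's bag label, is its context.  Labels are
first *collapsed* — preposition- and conjunction-specific relations like
``prep_in`` or ``conj_or`` reduce to their family labels ``prep`` / ``conj``
— and then *merged* upward through the dependency hierarchy, e.g. ``dobj``
and ``iobj`` both land in the ``obj`` bag.  Pairs sharing a bag label form a
context bag; unions of bags are the training data for the embedding models.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .conll import ParsedSentence

#: suffix marking an inverse (dependent-side) context, Levy-Goldberg style
INV_MARK = "-1"

#: canonical verb-related bag labels, in signature order
CANONICAL_BAGS = ("subj", "obj", "comp", "pcomp", "prep", "conj", "rel")

#: Stanford-typed labels folded into their canonical bags.  Only the bottom
#: levels of the hierarchy are folded; anything absent passes through.
DEFAULT_MERGE_TABLE: dict[str, str] = {
    "dobj": "obj",
    "iobj": "obj",
    "dative": "obj",
    "nsubj": "subj",
    "nsubjpass": "subj",
    "csubj": "subj",
    "csubjpass": "subj",
    "xcomp": "comp",
    "ccomp": "comp",
    "acomp": "comp",
    "rcmod": "rel",
    "relcl": "rel",
    "acl:relcl": "rel",
    "pcomp": "pcomp",
    "pobj": "prep",
}

#: labels carrying no lexical signal, dropped before pair construction
DEFAULT_DROP_SET = frozenset({"punct", "dep", "root"})

_PREP_RE = re.compile(r"^(prep|nmod)([_:].+)?$")
_CONJ_RE = re.compile(r"^conj([_:].+)?$")


def collapse_label(raw_deprel: str) -> str:
    """Collapse lexicalized prepositional/conjunction labels to their family.

    ``prep_in`` -> ``prep``; ``conj_or`` -> ``conj``; anything else is
    returned unchanged at this stage.
    """
    if not raw_deprel:
        raise ValueError("deprel must be non-empty")
    if _PREP_RE.match(raw_deprel):
        return "prep"
    if _CONJ_RE.match(raw_deprel):
        return "conj"
    return raw_deprel


def merge_label(
    collapsed_deprel: str, merge_table: Mapping[str, str] | None = None
) -> str:
    """Fold a collapsed label into its canonical context-bag label."""
    table = DEFAULT_MERGE_TABLE if merge_table is None else merge_table
    return table.get(collapsed_deprel, collapsed_deprel)


def canonical_bag(raw_deprel: str, merge_table: Mapping[str, str] | None = None) -> str:
    """collapse then merge — the full label normalization."""
    return merge_label(collapse_label(raw_deprel), merge_table)


@dataclass(frozen=True)
class WordContextPair:
    """A single SGNS training example, e.g. ``(modulator, efficient_amod)``."""

    word: str
    context: str
    bag: str

    def __post_init__(self) -> None:
        if not self.word or not self.context:
            raise ValueError("word and context must be non-empty")


@dataclass
class ContextBag:
    """All pairs sharing one canonical dependency label."""

    label: str
    pairs: list[WordContextPair] = field(default_factory=list)

    @property
    def pair_count(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the arc-to-pair conversion.

    ``inverse_contexts`` additionally emits the dependent-side pair
    ``(dependent, head_label-1)`` for every arc, so both endpoints of an arc
    receive a context.
    """

    merge_table: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MERGE_TABLE)
    )
    drop_set: frozenset[str] = DEFAULT_DROP_SET
    inverse_contexts: bool = True


def extract_pairs(
    sentence: ParsedSentence, rules: ExtractionConfig | None = None
) -> list[WordContextPair]:
    """Convert every retained dependency arc of a sentence into pairs.

    Words are normalized (lemma when present, else lowercased form).  Arcs
    whose canonical label lands in the drop set emit nothing.
    """
    rules = rules or ExtractionConfig()
    pairs: list[WordContextPair] = []
    for head, dep, deprel in sentence.arcs():
        label = canonical_bag(deprel, rules.merge_table)
        if label in rules.drop_set:
            continue
        w_head, w_dep = head.norm, dep.norm
        pairs.append(WordContextPair(w_head, f"{w_dep}_{label}", label))
        if rules.inverse_contexts:
            pairs.append(WordContextPair(w_dep, f"{w_head}_{label}{INV_MARK}", label))
    return pairs


def extract_corpus_pairs(
    sentences: Iterable[ParsedSentence], rules: ExtractionConfig | None = None
) -> list[WordContextPair]:
    rules = rules or ExtractionConfig()
    out: list[WordContextPair] = []
    for sent in sentences:
        out.extend(extract_pairs(sent, rules))
    return out


def filter_pairs(
    pairs: Sequence[WordContextPair],
    min_word_count: int = 100,
    min_pair_count: int = 1,
    word_counts: Mapping[str, int] | None = None,
) -> list[WordContextPair]:
    """Drop pairs with infrequent target words (and, optionally, rare pairs).

    ``min_word_count`` removes pairs whose target word occurs *fewer than*
    that many times — a word at exactly the threshold survives.  Frequencies
    default to target-word counts over the pair multiset; pass ``word_counts``
    to use corpus token counts instead.  ``min_pair_count`` applies the same
    strict-less-than rule to the multiplicity of the exact (word, context)
    pair; the default 1 keeps everything.
    """
    if min_word_count < 0:
        raise ValueError("min_word_count must be >= 0")
    if word_counts is None:
        word_counts = Counter(p.word for p in pairs)
    pair_counts: Counter | None = None
    if min_pair_count > 1:
        pair_counts = Counter((p.word, p.context) for p in pairs)
    kept = []
    for p in pairs:
        if word_counts.get(p.word, 0) < min_word_count:
            continue
        if pair_counts is not None and pair_counts[(p.word, p.context)] < min_pair_count:
            continue
        kept.append(p)
    return kept


def group_into_bags(pairs: Iterable[WordContextPair]) -> dict[str, ContextBag]:
    """Partition pairs by bag label; bag sizes sum to the input size."""
    bags: dict[str, ContextBag] = {}
    for p in pairs:
        bags.setdefault(p.bag, ContextBag(label=p.bag)).pairs.append(p)
    return bags


# ---------------------------------------------------------------------------
# pair-file format: 2-column TSV, one "word<TAB>context" per line, UTF-8,
# corpus order.  The bag label is recoverable from the context suffix.

def _bag_of_context(context: str) -> str:
    base = context[: -len(INV_MARK)] if context.endswith(INV_MARK) else context
    return base.rsplit("_", 1)[-1]


def write_pairs(pairs: Iterable[WordContextPair], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as out:
        for p in pairs:
            out.write(f"{p.word}\t{p.context}\n")
            n += 1
    return n


def read_pairs(path: str | Path) -> list[WordContextPair]:
    pairs = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            word, context = cols
            pairs.append(WordContextPair(word, context, _bag_of_context(context)))
    return pairs


def write_bag_manifest(bags: Mapping[str, ContextBag], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("bag\tpair_count\n")
        for label in sorted(bags):
            out.write(f"{label}\t{bags[label].pair_count}\n")


def write_bag_dir(bags: Mapping[str, ContextBag], out_dir: str | Path) -> None:
    """One pair file per bag (``<label>.pairs``) plus ``bags.tsv`` manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, bag in bags.items():
        write_pairs(bag.pairs, out_dir / f"{label}.pairs")
    write_bag_manifest(bags, out_dir / "bags.tsv")


def read_bag_dir(bag_dir: str | Path) -> dict[str, ContextBag]:
    bag_dir = Path(bag_dir)
    bags: dict[str, ContextBag] = {}
    for path in sorted(bag_dir.glob("*.pairs")):
        label = path.stem
        bags[label] = ContextBag(label=label, pairs=read_pairs(path))
    return bags
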