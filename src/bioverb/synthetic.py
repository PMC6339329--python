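"""Synthetic dependency-parsed corpora with planted verb-class structure.

Every pipeline stage needs a corpus whose ground truth is known: verbs are
partitioned into classes, and members of a class draw the dependents of
their *informative* relations (subject, object, preposition by default)
from a class-specific noun pool with probability ``signal_strength``, from a
shared global pool otherwise.  Noise relations (adjectival modifiers,
determiners, noun compounds) attach to nouns and are independent of the
verb's class, so they carry no verb signal — exactly the situation the
context-configuration search is meant to detect.

The planted signal is *complementary* across informative relations: with
two or more informative bags, each bag's noun pools are shared between a
group of classes (subjects partition the classes one way, objects another),
so that no single relation separates all classes but their union does.
This rewards the search for combining bags rather than settling on any
singleton.  Each sentence has one root verb; labels come from the
Stanford-typed inventory (``nsubjpass``, ``iobj``, ``prep_in``...) so the
collapse/merge paths are exercised.

From the ground truth the module also derives a verb-similarity gold table
(same-class pairs anchored high, cross-class pairs low) and a seed/candidate
lexicon split, emulating the resources the real pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import SeedLexicon, VerbClass
from .conll import ParsedSentence, ParsedToken, write_conll
from .similarity import SimilarityPair, save_gold

_SUBJ_LABELS = ("nsubj", "nsubj", "nsubj", "nsubj", "nsubjpass")
_OBJ_LABELS = ("dobj", "dobj", "dobj", "dobj", "dobj", "iobj")
_PREP_LABELS = ("prep_in", "prep_of", "prep_with", "prep_by")
_DETERMINERS = ("the", "a", "this")


@dataclass(frozen=True)
class SynthesisParams:
    """Shape and strength of the planted structure."""

    n_classes: int = 6
    verbs_per_class: int = 8
    noun_pool_per_class: int = 8
    n_sentences: int = 20_000
    informative_bags: frozenset[str] = frozenset({"subj", "obj", "prep"})
    noise_bags: frozenset[str] = frozenset({"amod", "nn", "det"})
    signal_strength: float = 0.95
    seed: int = 1
    shared_noun_pool: int = 40
    adjective_pool: int = 15
    modifier_pool: int = 15
    p_obj: float = 0.85
    p_prep: float = 0.6
    p_det: float = 0.5
    p_amod: float = 0.4
    p_nn: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.informative_bags & self.noise_bags:
            raise ValueError("informative and noise bag sets must be disjoint")
        if min(self.n_classes, self.verbs_per_class, self.noun_pool_per_class) < 1:
            raise ValueError("class/verb/pool sizes must be >= 1")
        if self.shared_noun_pool < 1:
            raise ValueError("shared_noun_pool must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: verb classes, pools, and the informative bag set."""

    verb_to_class: dict[str, int]
    class_pools: dict[int, list[str]]
    informative_bags: frozenset[str]

    @property
    def n_classes(self) -> int:
        return len(self.class_pools)

    def verbs_of_class(self, c: int) -> list[str]:
        return sorted(v for v, k in self.verb_to_class.items() if k == c)

    def save(self, path: str | Path) -> None:
        payload = {
            "verb_to_class": self.verb_to_class,
            "class_pools": {str(k): v for k, v in self.class_pools.items()},
            "informative_bags": sorted(self.informative_bags),
        }
        with open(path, "w", encoding="utf-8") as out:
            json.dump(payload, out, indent=1, sort_keys=True)
            out.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(
            verb_to_class=payload["verb_to_class"],
            class_pools={int(k): v for k, v in payload["class_pools"].items()},
            informative_bags=frozenset(payload["informative_bags"]),
        )


def _class_group(bag_rank: int, cls: int, n_classes: int, n_bags: int) -> int:
    """Which noun-pool group class ``cls`` uses for its ``bag_rank``-th bag.

    One informative bag carries full class identity; with several, the first
    bag indexes the class's "row" and the others its "column" in a near-
    square grid, so the (row, column) pair — but neither alone — pins down
    the class.
    """
    if n_bags == 1:
        return cls
    g = int(np.ceil(np.sqrt(n_classes)))
    return cls // g if bag_rank == 0 else cls % g


def _vocabulary(params: SynthesisParams):
    verbs = {
        c: [f"verb{c}x{i}" for i in range(params.verbs_per_class)]
        for c in range(params.n_classes)
    }
    bags_sorted = sorted(params.informative_bags)
    bag_pools: dict[str, dict[int, list[str]]] = {}
    for k, bag in enumerate(bags_sorted):
        groups = {
            _class_group(k, c, params.n_classes, len(bags_sorted))
            for c in range(params.n_classes)
        }
        bag_pools[bag] = {
            grp: [f"{bag}n{grp}x{j}" for j in range(params.noun_pool_per_class)]
            for grp in groups
        }
    class_pools = {
        c: sorted(
            {
                noun
                for k, bag in enumerate(bags_sorted)
                for noun in bag_pools[bag][
                    _class_group(k, c, params.n_classes, len(bags_sorted))
                ]
            }
        )
        for c in range(params.n_classes)
    }
    shared = [f"gnoun{j}" for j in range(params.shared_noun_pool)]
    adjectives = [f"adj{j}" for j in range(params.adjective_pool)]
    modifiers = [f"mod{j}" for j in range(params.modifier_pool)]
    return verbs, bag_pools, class_pools, shared, adjectives, modifiers


def generate(params: SynthesisParams) -> tuple[list[ParsedSentence], GroundTruth]:
    """Build the corpus and its ground truth; reproducible under the seed."""
    rng = np.random.default_rng(params.seed)
    verbs, bag_pools, class_pools, shared, adjectives, modifiers = _vocabulary(params)
    truth = GroundTruth(
        verb_to_class={v: c for c, vs in verbs.items() for v in vs},
        class_pools=class_pools,
        informative_bags=frozenset(params.informative_bags),
    )
    bag_rank = {bag: k for k, bag in enumerate(sorted(params.informative_bags))}

    def pick_noun(bag: str, cls: int) -> str:
        if bag in params.informative_bags and rng.random() < params.signal_strength:
            grp = _class_group(
                bag_rank[bag], cls, params.n_classes, len(bag_rank)
            )
            pool = bag_pools[bag][grp]
        else:
            pool = shared
        return pool[rng.integers(len(pool))]

    sentences: list[ParsedSentence] = []
    for s in range(params.n_sentences):
        cls = int(rng.integers(params.n_classes))
        verb = verbs[cls][rng.integers(params.verbs_per_class)]
        # token spec rows: [form, pos, head (patched later), deprel]
        rows: list[list] = []

        def add_np(bag: str, deprel: str) -> int:
            """Append a noun phrase; head of the noun is patched by caller.

            Returns the 1-based index of the head noun.  Noise modifiers
            attach to the noun and are emitted only for enabled noise bags.
            """
            mods: list[list] = []
            if "det" in params.noise_bags and rng.random() < params.p_det:
                mods.append([_DETERMINERS[rng.integers(len(_DETERMINERS))], "DET", 0, "det"])
            if "amod" in params.noise_bags and rng.random() < params.p_amod:
                mods.append([adjectives[rng.integers(len(adjectives))], "ADJ", 0, "amod"])
            if "nn" in params.noise_bags and rng.random() < params.p_nn:
                mods.append([shared[rng.integers(len(shared))], "NOUN", 0, "nn"])
            noun_idx = len(rows) + len(mods) + 1
            for m in mods:
                m[2] = noun_idx
                rows.append(m)
            rows.append([pick_noun(bag, cls), "NOUN", 0, deprel])
            return noun_idx

        subj_idx = add_np("subj", _SUBJ_LABELS[rng.integers(len(_SUBJ_LABELS))])
        verb_idx = len(rows) + 1
        rows.append([verb, "VERB", 0, "root"])
        rows[subj_idx - 1][2] = verb_idx
        if rng.random() < params.p_obj:
            obj_idx = add_np("obj", _OBJ_LABELS[rng.integers(len(_OBJ_LABELS))])
            rows[obj_idx - 1][2] = verb_idx
        if rng.random() < params.p_prep:
            prep_idx = add_np("prep", _PREP_LABELS[rng.integers(len(_PREP_LABELS))])
            rows[prep_idx - 1][2] = verb_idx

        tokens = [
            ParsedToken(index=i + 1, form=form, lemma=form, pos=pos, head=head, deprel=rel)
            for i, (form, pos, head, rel) in enumerate(rows)
        ]
        sent = ParsedSentence(tokens=tokens, sent_id=f"s{s + 1}")
        sent.validate()
        sentences.append(sent)
    return sentences, truth


def derive_gold(
    truth: GroundTruth,
    n_pairs: int,
    seed: int,
    high_anchor: float = 1.0,
    low_anchor: float = 0.0,
    jitter: float = 0.05,
) -> list[SimilarityPair]:
    """Sample verb pairs scored high (same class) or low (different class).

    Same- and cross-class pairs are balanced as far as supply allows;
    Gaussian jitter (sd = ``jitter``) breaks ties so ranks are informative.
    """
    rng = np.random.default_rng(seed)
    all_verbs = sorted(truth.verb_to_class)
    if len(all_verbs) < 2:
        raise ValueError("need at least 2 verbs")
    same, diff = [], []
    for i, v1 in enumerate(all_verbs):
        for v2 in all_verbs[i + 1 :]:
            (same if truth.verb_to_class[v1] == truth.verb_to_class[v2] else diff).append(
                (v1, v2)
            )
    if n_pairs > len(same) + len(diff):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds the {len(same) + len(diff)} distinct pairs"
        )
    n_same = min(n_pairs // 2, len(same))
    n_diff = min(n_pairs - n_same, len(diff))
    n_same = n_pairs - n_diff  # top up if cross-class supply was short
    chosen = [
        (same[i], high_anchor)
        for i in rng.choice(len(same), size=n_same, replace=False)
    ] + [
        (diff[i], low_anchor)
        for i in rng.choice(len(diff), size=n_diff, replace=False)
    ]
    pairs = []
    for (v1, v2), anchor in chosen:
        score = anchor + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        pairs.append(SimilarityPair(v1, v2, float(score)))
    return pairs


def split_lexicon(
    truth: GroundTruth, seeds_per_class: int, seed: int
) -> tuple[SeedLexicon, list[str]]:
    """Split each planted class into seed members and held-out candidates."""
    if seeds_per_class < 1:
        raise ValueError("seeds_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    classes: dict[str, VerbClass] = {}
    candidates: list[str] = []
    for c in sorted(truth.class_pools):
        members = truth.verbs_of_class(c)
        if seeds_per_class >= len(members):
            raise ValueError(
                f"class {c}: seeds_per_class={seeds_per_class} leaves no "
                f"candidates out of {len(members)} verbs"
            )
        order = rng.permutation(len(members))
        seeds = sorted(members[i] for i in order[:seeds_per_class])
        rest = sorted(members[i] for i in order[seeds_per_class:])
        classes[f"{c + 1}.1.0"] = VerbClass(name=f"planted-class-{c}", members=seeds)
        candidates.extend(rest)
    return SeedLexicon(classes=classes), sorted(candidates)


def class_index_of(truth: GroundTruth, verb: str) -> str:
    """The dotted class index ``split_lexicon`` gives the verb's true class."""
    return f"{truth.verb_to_class[verb] + 1}.1.0"


def write_dataset(params: SynthesisParams, out_dir: str | Path,
                  n_gold_pairs: int = 300, seeds_per_class: int = 3) -> dict[str, Path]:
    """Generate and write the full bundle: corpus, gold, lexicon split, truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sentences, truth = generate(params)
    n_verbs = params.n_classes * params.verbs_per_class
    n_gold_pairs = min(n_gold_pairs, n_verbs * (n_verbs - 1) // 2)
    paths = {
        "corpus": out_dir / "corpus.conllu",
        "gold": out_dir / "gold.tsv",
        "seed_lexicon": out_dir / "seed.tsv",
        "candidates": out_dir / "candidates.txt",
        "truth": out_dir / "truth.json",
    }
    write_conll(sentences, paths["corpus"])
    save_gold(derive_gold(truth, n_gold_pairs, params.seed), paths["gold"])
    lexicon, candidates = split_lexicon(truth, seeds_per_class, params.seed)
    lexicon.save_tsv(paths["seed_lexicon"])
    paths["candidates"].write_text("\n".join(candidates) + "\n", encoding="utf-8")
    truth.save(paths["truth"])
    return paths
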