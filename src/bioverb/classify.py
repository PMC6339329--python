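"""Expanding a VerbNet-style seed classification by nearest-centroid search.

Each seed class (a dotted index such as ``2.2.1``, a name, and member verbs)
is represented by the centroid — the arithmetic mean — of its members'
vectors; candidate verbs are assigned to the class whose centroid is nearest
in euclidean distance.  The module also produces the human-review materials:
per-verb dependency-context signatures such as ``subj#obj`` and example
sentences (up to three per top-10 signature, thirty in all).
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conll import ParsedSentence
from .contexts import CANONICAL_BAGS, DEFAULT_DROP_SET, canonical_bag
from .embeddings import WordVectorSet


@dataclass
class VerbClass:
    name: str
    members: list[str]
    candidates: list[str] = field(default_factory=list)


@dataclass
class SeedLexicon:
    """class index -> (name, member verbs); the classification being expanded."""

    classes: dict[str, VerbClass]

    def __post_init__(self) -> None:
        for idx, cls in self.classes.items():
            if not cls.members:
                raise ValueError(f"class {idx} has no members")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_verbs(self) -> int:
        return sum(len(c.members) + len(c.candidates) for c in self.classes.values())

    def all_seed_verbs(self) -> set[str]:
        return {v for c in self.classes.values() for v in c.members}

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            out.write("class_index\tclass_name\tverb\torigin\n")
            for idx in sorted(self.classes):
                cls = self.classes[idx]
                for v in cls.members:
                    out.write(f"{idx}\t{cls.name}\t{v}\tseed\n")
                for v in cls.candidates:
                    out.write(f"{idx}\t{cls.name}\t{v}\tcandidate\n")

    def save_json(self, path: str | Path) -> None:
        payload = {
            idx: {
                "name": cls.name,
                "members": cls.members,
                "candidates": cls.candidates,
            }
            for idx, cls in sorted(self.classes.items())
        }
        with open(path, "w", encoding="utf-8") as out:
            json.dump(payload, out, indent=1, sort_keys=True)
            out.write("\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "SeedLexicon":
        classes: dict[str, VerbClass] = {}
        with open(path, encoding="utf-8") as handle:
            header = handle.readline().rstrip("\n").split("\t")
            cols = {name: i for i, name in enumerate(header)}
            for lineno, line in enumerate(handle, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                idx = parts[cols["class_index"]]
                name = parts[cols["class_name"]]
                verb = parts[cols["verb"]]
                origin = parts[cols["origin"]] if "origin" in cols else "seed"
                vc = classes.setdefault(idx, VerbClass(name=name, members=[]))
                (vc.members if origin == "seed" else vc.candidates).append(verb)
        return cls(classes=classes)


@dataclass(frozen=True)
class ClassCentroid:
    class_index: str
    vector: np.ndarray
    n_members_used: int


@dataclass(frozen=True)
class Assignment:
    verb: str
    class_index: str
    distance: float
    runner_up_index: str | None
    margin: float


def compute_centroids(
    lexicon: SeedLexicon, vectors: WordVectorSet
) -> dict[str, ClassCentroid]:
    """Mean of in-vocabulary member vectors per class; OOV members skipped.

    A class with no member in the vocabulary cannot be represented and
    raises, naming the class.
    """
    centroids: dict[str, ClassCentroid] = {}
    for idx in sorted(lexicon.classes):
        cls = lexicon.classes[idx]
        rows = [vectors[v] for v in cls.members if v in vectors]
        oov = [v for v in cls.members if v not in vectors]
        if not rows:
            raise ValueError(
                f"class {idx} ({cls.name}): no member verb in vocabulary "
                f"(members: {', '.join(cls.members)})"
            )
        if oov:
            warnings.warn(
                f"class {idx}: skipping out-of-vocabulary members {oov}",
                stacklevel=2,
            )
        centroids[idx] = ClassCentroid(
            class_index=idx,
            vector=np.mean(rows, axis=0),
            n_members_used=len(rows),
        )
    return centroids


def assign(
    candidates: Sequence[str],
    centroids: Mapping[str, ClassCentroid],
    vectors: WordVectorSet,
) -> tuple[list[Assignment], list[str]]:
    """Nearest-centroid assignment of in-vocabulary candidates.

    Ties break toward the lexicographically smallest class index.  Returns
    the assignments and the out-of-vocabulary candidates (reported, never
    force-assigned).
    """
    if not centroids:
        raise ValueError("empty centroid set")
    indices = sorted(centroids)  # stable order makes the tie-break rule exact
    matrix = np.stack([centroids[i].vector for i in indices])
    assignments: list[Assignment] = []
    oov: list[str] = []
    for verb in candidates:
        vec = vectors.get(verb)
        if vec is None:
            oov.append(verb)
            continue
        dists = np.linalg.norm(matrix - vec, axis=1)
        order = np.argsort(dists, kind="stable")
        best = int(order[0])
        runner = int(order[1]) if len(order) > 1 else None
        assignments.append(
            Assignment(
                verb=verb,
                class_index=indices[best],
                distance=float(dists[best]),
                runner_up_index=None if runner is None else indices[runner],
                margin=0.0 if runner is None else float(dists[runner] - dists[best]),
            )
        )
    return assignments, oov


def expand_lexicon(
    lexicon: SeedLexicon, assignments: Sequence[Assignment]
) -> SeedLexicon:
    """Attach assigned candidates to their classes, keeping seeds separate.

    A candidate that duplicates a seed verb (or an earlier candidate) is
    dropped with a warning, so total verb count = seeds + distinct new
    candidates.
    """
    expanded = SeedLexicon(
        classes={
            idx: VerbClass(name=c.name, members=list(c.members), candidates=list(c.candidates))
            for idx, c in lexicon.classes.items()
        }
    )
    seen = expanded.all_seed_verbs() | {
        v for c in expanded.classes.values() for v in c.candidates
    }
    for a in assignments:
        if a.class_index not in expanded.classes:
            raise ValueError(f"assignment to unknown class index {a.class_index}")
        if a.verb in seen:
            warnings.warn(
                f"candidate {a.verb!r} already present in the lexicon; dropped",
                stacklevel=2,
            )
            continue
        expanded.classes[a.class_index].candidates.append(a.verb)
        seen.add(a.verb)
    return expanded


# ---------------------------------------------------------------------------
# human-review materials

_SIG_ORDER = {label: i for i, label in enumerate(CANONICAL_BAGS)}


def _sentence_signature(
    sentence: ParsedSentence, verb: str, drop_set=DEFAULT_DROP_SET
) -> str | None:
    """The ``#``-joined set of bag labels the verb governs in this sentence."""
    labels: set[str] = set()
    found = False
    for head, dep, deprel in sentence.arcs():
        if head.norm != verb:
            continue
        found = True
        label = canonical_bag(deprel)
        if label not in drop_set:
            labels.add(label)
    if not found or not labels:
        return None
    ordered = sorted(labels, key=lambda l: (_SIG_ORDER.get(l, len(_SIG_ORDER)), l))
    return "#".join(ordered)


def context_signature(
    verb: str, corpus: Iterable[ParsedSentence], top_n: int = 10
) -> list[tuple[str, int]]:
    """Top-``top_n`` dependency-context signatures of a verb, by frequency.

    Duplicate labels within one sentence collapse (two ``prep`` dependents
    still yield one ``prep`` in the signature).  An absent verb yields an
    empty list.  Frequency ties break by first occurrence in corpus order.
    """
    counts: Counter[str] = Counter()
    first_seen: dict[str, int] = {}
    for i, sent in enumerate(corpus):
        sig = _sentence_signature(sent, verb)
        if sig is not None:
            counts[sig] += 1
            first_seen.setdefault(sig, i)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], first_seen[kv[0]]))
    return ranked[:top_n]


@dataclass
class ReviewSheet:
    """Support material for expert validation of one verb."""

    verb: str
    top_contexts: list[tuple[str, int]]
    examples: dict[str, list[str]]  # signature -> up to 3 example sentences

    @property
    def n_sentences(self) -> int:
        return sum(len(v) for v in self.examples.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "verb": self.verb,
            "top_contexts": [
                {"signature": s, "frequency": f} for s, f in self.top_contexts
            ],
            "examples": self.examples,
        }
        with open(path, "w", encoding="utf-8") as out:
            json.dump(payload, out, indent=1)
            out.write("\n")


def build_review_sheet(
    verb: str,
    corpus: Sequence[ParsedSentence],
    top_n: int = 10,
    per_signature: int = 3,
) -> ReviewSheet:
    """Up to ``per_signature`` example sentences per top signature.

    With 10 signatures and 3 examples each this is the 30-sentence review
    packet.  Examples are the first occurrences in corpus order, so output
    is deterministic.
    """
    top = context_signature(verb, corpus, top_n=top_n)
    wanted = {sig for sig, _ in top}
    examples: dict[str, list[str]] = {sig: [] for sig, _ in top}
    for sent in corpus:
        sig = _sentence_signature(sent, verb)
        if sig in wanted and len(examples[sig]) < per_signature:
            examples[sig].append(" ".join(t.form for t in sent.tokens))
    return ReviewSheet(verb=verb, top_contexts=top, examples=examples)
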