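"""Context-configuration search.

A *configuration* is a non-empty set of context-bag labels; a model trained
on the union of those bags is scored by Spearman rho against a verb
similarity gold standard.  The search has two stages:

1. **Singleton filter** — one model per individual bag; bags whose singleton
   rho falls below a threshold (0.2 by default) are discarded as
   uninformative for verbs.  The survivors form the initial configuration.
2. **Beam descent** — starting from the full M-set configuration, every
   (M-1)-set child with one bag removed is scored; only children that
   strictly outperform their parent stay on the frontier, and the descent
   repeats until the singleton level or an empty frontier.  Scores are
   memoized so no configuration is ever trained twice.

The exhaustive alternative would cost 2^M - 1 trained models; the descent
visits a small fraction of that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .contexts import ContextBag, WordContextPair
from .embeddings import TrainingConfig, WordVectorSet, train_sgns
from .similarity import (
    EvaluationResult,
    InsufficientCoverageError,
    SimilarityPair,
    evaluate,
    load_gold,
)

Configuration = frozenset[str]
Scorer = Callable[[Configuration], float]


@dataclass(frozen=True)
class ScoredConfiguration:
    bags: Configuration
    score: float
    level: int  # configuration size

    def as_dict(self) -> dict:
        return {"bags": sorted(self.bags), "rho": self.score, "level": self.level}


@dataclass
class SearchTrace:
    """Every configuration visited, in visit order, plus the winner."""

    visited: list[ScoredConfiguration] = field(default_factory=list)
    total_possible: int = 0
    baselines: dict[str, float] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> ScoredConfiguration:
        if not self.visited:
            raise ValueError("empty trace")
        return max(self.visited, key=lambda s: s.score)

    @property
    def n_visited(self) -> int:
        return len(self.visited)

    def save(self, path: str | Path) -> None:
        payload = {
            "visited": [s.as_dict() for s in self.visited],
            "best": self.best.as_dict(),
            "total_possible": self.total_possible,
            "baselines": self.baselines,
            "notes": self.notes,
        }
        with open(path, "w", encoding="utf-8") as out:
            json.dump(payload, out, indent=1, sort_keys=True)
            out.write("\n")


def count_all_configurations(M: int) -> int:
    """Number of non-empty bag subsets: 2^M - 1 (1023 for M=10, 127 for M=7)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return 2**M - 1


class NoBagSurvivesError(ValueError):
    """Every singleton configuration scored below the filter threshold."""


def filter_bags(
    labels: Sequence[str], scorer: Scorer, threshold: float = 0.2
) -> tuple[set[str], dict[str, float]]:
    """Keep labels whose singleton-configuration score is >= threshold.

    Trains/evaluates exactly one model per bag.  Returns the surviving label
    set and all singleton scores (for trace accounting).
    """
    scores = {label: scorer(frozenset([label])) for label in labels}
    kept = {label for label, s in scores.items() if s >= threshold}
    if not kept:
        raise NoBagSurvivesError(
            f"no context bag reaches the singleton threshold {threshold}; "
            f"best was {max(scores.values()):.4f} — lower the threshold"
        )
    return kept, scores


def beam_descent(
    initial: Configuration,
    scorer: Scorer,
    memo: dict[Configuration, float] | None = None,
) -> SearchTrace:
    """Descend from ``initial`` removing one bag at a time.

    A child joins the next frontier only if its score strictly exceeds its
    parent's.  ``memo`` (shared, mutated) guarantees each configuration is
    scored at most once; pre-seed it with singleton scores to avoid
    re-training at the lowest level.
    """
    if not initial:
        raise ValueError("initial configuration must be non-empty")
    memo = {} if memo is None else memo
    trace = SearchTrace(total_possible=count_all_configurations(len(initial)))
    seen_in_trace: set[Configuration] = set()

    def score(cfg: Configuration) -> float:
        if cfg not in memo:
            memo[cfg] = scorer(cfg)
        if cfg not in seen_in_trace:
            seen_in_trace.add(cfg)
            trace.visited.append(ScoredConfiguration(cfg, memo[cfg], len(cfg)))
        return memo[cfg]

    frontier = [initial]
    score(initial)
    while frontier:
        next_frontier: list[Configuration] = []
        for parent in frontier:
            if len(parent) <= 1:
                continue
            parent_score = memo[parent]
            for bag in sorted(parent):
                child = parent - {bag}
                if score(child) > parent_score and child not in next_frontier:
                    next_frontier.append(child)
        frontier = next_frontier
    return trace


def make_sgns_scorer(
    bags: Mapping[str, ContextBag],
    gold: Sequence[SimilarityPair],
    train_cfg: TrainingConfig,
    keep_vectors_for: Configuration | None = None,
) -> tuple[Scorer, dict]:
    """Scorer: train SGNS on the union of a configuration's bags, eval vs gold.

    One fixed seed is shared across configurations so score differences
    reflect the contexts, not sampling noise.  A configuration whose model
    covers fewer than two gold pairs scores -1.0 (recorded in ``info``).
    """
    info: dict = {"insufficient_coverage": [], "vectors": {}}

    def scorer(cfg: Configuration) -> float:
        pairs: list[WordContextPair] = []
        for label in sorted(cfg):
            if label in bags:
                pairs.extend(bags[label].pairs)
        if not pairs:
            info["insufficient_coverage"].append(sorted(cfg))
            return -1.0
        try:
            vectors = train_sgns(pairs, train_cfg)
            result = evaluate(vectors, gold)
        except (InsufficientCoverageError, ValueError):
            info["insufficient_coverage"].append(sorted(cfg))
            return -1.0
        if keep_vectors_for is not None and cfg == keep_vectors_for:
            info["vectors"][cfg] = vectors
        return result.rho

    return scorer, info


def run_search(
    bags: Mapping[str, ContextBag],
    gold: Sequence[SimilarityPair],
    train_cfg: TrainingConfig,
    threshold: float = 0.2,
) -> tuple[SearchTrace, WordVectorSet]:
    """Full pipeline: singleton filter, beam descent, final model training.

    The trace also records two baselines: DEP-ALL (every bag, no filtering)
    and POOL-ALL (the union of all threshold-surviving bags).  Returns the
    trace and the vectors of the best configuration found.
    """
    scorer, info = make_sgns_scorer(bags, gold, train_cfg)
    kept, singleton_scores = filter_bags(sorted(bags), scorer, threshold)

    memo: dict[Configuration, float] = {
        frozenset([label]): s for label, s in singleton_scores.items()
    }
    initial = frozenset(kept)
    trace = beam_descent(initial, scorer, memo=memo)

    # prepend singleton stage so trace accounting covers every trained model
    beam_set = {s.bags for s in trace.visited}
    singles = [
        ScoredConfiguration(frozenset([label]), s, 1)
        for label, s in sorted(singleton_scores.items())
        if frozenset([label]) not in beam_set
    ]
    trace.visited = singles + trace.visited
    trace.total_possible = count_all_configurations(len(bags))

    def scored(cfg: Configuration) -> float:
        if cfg not in memo:
            memo[cfg] = scorer(cfg)
        return memo[cfg]

    trace.baselines["DEP-ALL"] = scored(frozenset(bags))
    trace.baselines["POOL-ALL"] = scored(initial)
    trace.notes["initial_configuration"] = "+".join(sorted(initial))
    trace.notes["threshold"] = str(threshold)

    best = trace.best
    final_pairs: list[WordContextPair] = []
    for label in sorted(best.bags):
        final_pairs.extend(bags[label].pairs)
    vectors = train_sgns(final_pairs, train_cfg)
    return trace, vectors
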