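"""Scoring vector sets against a verb-similarity gold standard.

The protocol mirrors standard word-similarity evaluation (SimLex / SimVerb
style): for every gold verb pair with both verbs in the model vocabulary,
the model similarity is the cosine of their vectors; model and human scores
are then compared by Spearman's rank correlation.  Pairs with an
out-of-vocabulary verb are skipped and reported as reduced coverage, never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .embeddings import WordVectorSet, cosine


@dataclass(frozen=True)
class SimilarityPair:
    verb1: str
    verb2: str
    human_score: float

    def __post_init__(self) -> None:
        if self.verb1 == self.verb2:
            raise ValueError(f"pair members must differ: {self.verb1!r}")
        if not np.isfinite(self.human_score):
            raise ValueError("human_score must be finite")


@dataclass(frozen=True)
class EvaluationResult:
    rho: float
    n_used: int
    n_skipped: int

    @property
    def coverage(self) -> float:
        total = self.n_used + self.n_skipped
        return self.n_used / total if total else 0.0


class InsufficientCoverageError(ValueError):
    """Fewer than two gold pairs could be scored against the model."""


def load_gold(path: str | Path) -> list[SimilarityPair]:
    """Read a 3-column TSV (verb1, verb2, score); optional header row."""
    pairs: list[SimilarityPair] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            if lineno == 1 and not _is_number(cols[2]):
                continue  # header
            if not _is_number(cols[2]):
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score {cols[2]!r}"
                )
            pairs.append(SimilarityPair(cols[0], cols[1], float(cols[2])))
    return pairs


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def save_gold(pairs: Sequence[SimilarityPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for p in pairs:
            out.write(f"{p.verb1}\t{p.verb2}\t{p.human_score:.6f}\n")


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average-ties ranks.

    Without ties this equals ``1 - 6*sum(d^2)/(n*(n^2-1))`` for rank
    differences ``d``.  Constant input has no defined ranking and raises.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def evaluate(vectors: WordVectorSet, gold: Sequence[SimilarityPair]) -> EvaluationResult:
    """Spearman rho of model cosines vs human scores over in-vocabulary pairs."""
    if not gold:
        raise ValueError("gold standard is empty")
    model_scores: list[float] = []
    human_scores: list[float] = []
    n_skipped = 0
    for pair in gold:
        v1 = vectors.get(pair.verb1)
        v2 = vectors.get(pair.verb2)
        if v1 is None or v2 is None:
            n_skipped += 1
            continue
        model_scores.append(cosine(v1, v2))
        human_scores.append(pair.human_score)
    n_used = len(model_scores)
    if n_used < 2:
        raise InsufficientCoverageError(
            f"only {n_used}/{len(gold)} gold pairs in vocabulary "
            f"(coverage {n_used / len(gold):.2%}); cannot rank"
        )
    rho = spearman(model_scores, human_scores)
    return EvaluationResult(rho=rho, n_used=n_used, n_skipped=n_skipped)
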