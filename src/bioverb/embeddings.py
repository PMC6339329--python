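"""Skip-gram negative-sampling (SGNS) training over (word, context) pairs.

The model keeps two matrices, word vectors ``W`` and context vectors ``C``.
For each observed pair (w, c) the objective contributes

    log sigma(W_w . C_c)  +  sum_{i=1..k} E_{c' ~ P_n} log sigma(-W_w . C_c')

where the noise distribution ``P_n`` is the context unigram distribution
raised to a smoothing exponent (0.75 by default).  Optimization is plain SGD
with a linearly decaying learning rate, exactly the word2vec recipe, run
single-threaded in fixed pair order so that a fixed seed gives bit-identical
vectors.  Bag-of-words training is the same trainer applied to pairs
enumerated from symmetric token windows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .contexts import WordContextPair

_SIGMOID_TABLE_SIZE = 2048
_SIGMOID_MAX = 8.0


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the SGNS trainer.

    ``negatives`` noise samples are drawn per positive pair from the
    smoothed context-frequency distribution.  ``min_count`` prunes words and
    contexts independently (an entry occurring fewer than ``min_count`` times
    is discarded).  ``window`` only matters for bag-of-words training.
    """

    dim: int = 300
    negatives: int = 15
    epochs: int = 5
    learning_rate: float = 0.025
    smoothing_exponent: float = 0.75
    subsample_threshold: float = 0.0
    seed: int = 1
    window: int = 5
    min_count: int = 100

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.smoothing_exponent <= 1.0:
            raise ValueError("smoothing_exponent must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class Vocabulary:
    """Contiguous integer ids and frequencies for words and contexts."""

    word_to_id: dict[str, int]
    context_to_id: dict[str, int]
    word_freq: np.ndarray
    context_freq: np.ndarray

    @property
    def words(self) -> list[str]:
        return list(self.word_to_id)

    @classmethod
    def build(
        cls, pairs: Sequence[tuple[str, str]], min_count: int
    ) -> "Vocabulary":
        wc: Counter[str] = Counter()
        cc: Counter[str] = Counter()
        for w, c in pairs:
            wc[w] += 1
            cc[c] += 1
        words = sorted(w for w, n in wc.items() if n >= min_count)
        contexts = sorted(c for c, n in cc.items() if n >= min_count)
        return cls(
            word_to_id={w: i for i, w in enumerate(words)},
            context_to_id={c: i for i, c in enumerate(contexts)},
            word_freq=np.array([wc[w] for w in words], dtype=np.int64),
            context_freq=np.array([cc[c] for c in contexts], dtype=np.int64),
        )


class WordVectorSet:
    """A word -> dense-vector mapping; the trained artifact."""

    def __init__(self, words: Sequence[str], matrix: np.ndarray):
        if len(words) != matrix.shape[0]:
            raise ValueError("one row per word required")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("vectors must be finite")
        self.words = list(words)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.index = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __len__(self) -> int:
        return len(self.words)

    def __getitem__(self, word: str) -> np.ndarray:
        return self.matrix[self.index[word]]

    def get(self, word: str) -> np.ndarray | None:
        i = self.index.get(word)
        return None if i is None else self.matrix[i]

    def save(self, path: str | Path) -> None:
        """word2vec text format: header ``N dim``, then one word per line."""
        with open(path, "w", encoding="utf-8") as out:
            out.write(f"{len(self.words)} {self.dim}\n")
            for w, row in zip(self.words, self.matrix):
                out.write(w + " " + " ".join(f"{v:.8f}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WordVectorSet":
        with open(path, encoding="utf-8") as handle:
            header = handle.readline().split()
            n, dim = int(header[0]), int(header[1])
            words, rows = [], np.empty((n, dim), dtype=np.float64)
            for i in range(n):
                cols = handle.readline().rstrip("\n").split(" ")
                words.append(cols[0])
                rows[i] = [float(v) for v in cols[1 : dim + 1]]
        return cls(words, rows)


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity of two non-zero vectors, in [-1, 1]."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))


@njit(cache=False)
def _sgns_epochs(
    w_ids,
    c_ids,
    W,
    C,
    noise_table,
    negatives,
    epochs,
    lr0,
    seed,
    sig_table,
    keep_prob,
):  # pragma: no cover - exercised through train_sgns
    state = np.uint64(seed * np.uint64(2654435769) + np.uint64(1))
    n_pairs = w_ids.shape[0]
    dim = W.shape[1]
    total = np.float64(epochs * n_pairs)
    table_n = noise_table.shape[0]
    step = 0
    for _ in range(epochs):
        for i in range(n_pairs):
            step += 1
            # xorshift64* PRNG — deterministic across platforms
            state ^= state >> np.uint64(12)
            state ^= state << np.uint64(25)
            state ^= state >> np.uint64(27)
            rnd = state * np.uint64(2685821657736338717)
            if keep_prob[w_ids[i]] < 1.0:
                u = np.float64(rnd >> np.uint64(11)) / np.float64(9007199254740992.0)
                if u >= keep_prob[w_ids[i]]:
                    continue
            lr = lr0 * (1.0 - np.float64(step - 1) / total)
            if lr < lr0 * 1e-4:
                lr = lr0 * 1e-4
            w = w_ids[i]
            grad_w = np.zeros(dim)
            for k in range(negatives + 1):
                if k == 0:
                    c = c_ids[i]
                    label = 1.0
                else:
                    state ^= state >> np.uint64(12)
                    state ^= state << np.uint64(25)
                    state ^= state >> np.uint64(27)
                    rnd = state * np.uint64(2685821657736338717)
                    c = noise_table[int(rnd % np.uint64(table_n))]
                    if c == c_ids[i]:
                        continue
                    label = 0.0
                dot = 0.0
                for d in range(dim):
                    dot += W[w, d] * C[c, d]
                if dot > _SIGMOID_MAX:
                    sig = 1.0
                elif dot < -_SIGMOID_MAX:
                    sig = 0.0
                else:
                    idx = int(
                        (dot + _SIGMOID_MAX)
                        / (2.0 * _SIGMOID_MAX)
                        * (_SIGMOID_TABLE_SIZE - 1)
                    )
                    sig = sig_table[idx]
                g = lr * (label - sig)
                for d in range(dim):
                    grad_w[d] += g * C[c, d]
                    C[c, d] += g * W[w, d]
            for d in range(dim):
                W[w, d] += grad_w[d]


def _build_noise_table(
    context_freq: np.ndarray, exponent: float, size: int = 1_000_000
) -> np.ndarray:
    probs = context_freq.astype(np.float64) ** exponent
    probs /= probs.sum()
    counts = np.maximum(1, np.round(probs * size)).astype(np.int64)
    return np.repeat(np.arange(len(context_freq), dtype=np.int64), counts)


def train_sgns(
    pairs: Sequence[WordContextPair] | Sequence[tuple[str, str]],
    config: TrainingConfig | None = None,
) -> WordVectorSet:
    """Train SGNS vectors on a (word, context) pair multiset.

    Raises ``ValueError`` if no pair survives vocabulary pruning.  With a
    fixed seed the output is bit-reproducible: single thread, fixed pair
    order, own PRNG.
    """
    config = config or TrainingConfig()
    raw: list[tuple[str, str]] = [
        (p.word, p.context) if isinstance(p, WordContextPair) else (p[0], p[1])
        for p in pairs
    ]
    vocab = Vocabulary.build(raw, config.min_count)
    if not vocab.word_to_id or not vocab.context_to_id:
        raise ValueError(
            "vocabulary empty after pruning "
            f"(min_count={config.min_count}); lower min_count or add data"
        )
    kept = [
        (vocab.word_to_id[w], vocab.context_to_id[c])
        for w, c in raw
        if w in vocab.word_to_id and c in vocab.context_to_id
    ]
    if not kept:
        raise ValueError("no training pair survives vocabulary pruning")
    w_ids = np.array([w for w, _ in kept], dtype=np.int64)
    c_ids = np.array([c for _, c in kept], dtype=np.int64)

    rng = np.random.RandomState(config.seed % (2**31))
    n_w = len(vocab.word_to_id)
    n_c = len(vocab.context_to_id)
    W = (rng.rand(n_w, config.dim) - 0.5) / config.dim
    C = np.zeros((n_c, config.dim), dtype=np.float64)

    noise_table = _build_noise_table(vocab.context_freq, config.smoothing_exponent)
    x = np.linspace(-_SIGMOID_MAX, _SIGMOID_MAX, _SIGMOID_TABLE_SIZE)
    sig_table = 1.0 / (1.0 + np.exp(-x))

    # word-frequency subsampling, word2vec-style keep probability
    keep_prob = np.ones(n_w, dtype=np.float64)
    if config.subsample_threshold > 0:
        freq = vocab.word_freq / vocab.word_freq.sum()
        ratio = config.subsample_threshold / freq
        keep_prob = np.minimum(1.0, np.sqrt(ratio) + ratio)

    _sgns_epochs(
        w_ids,
        c_ids,
        W,
        C,
        noise_table,
        config.negatives,
        config.epochs,
        config.learning_rate,
        config.seed % (2**31) + 1,
        sig_table,
        keep_prob,
    )
    if not np.all(np.isfinite(W)):
        raise FloatingPointError("non-finite word vectors after SGD update loop")
    return WordVectorSet(vocab.words, W)


def window_pairs(
    sentences: Iterable[Sequence[str]], window: int
) -> list[tuple[str, str]]:
    """Enumerate symmetric bag-of-words pairs, clipped at sentence bounds."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[tuple[str, str]] = []
    for sent in sentences:
        n = len(sent)
        for i, w in enumerate(sent):
            lo = max(0, i - window)
            hi = min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    out.append((w, sent[j]))
    return out


def train_bow(
    sentences: Iterable[Sequence[str]], config: TrainingConfig | None = None
) -> WordVectorSet:
    """Plain windowed SGNS: contexts are neighbouring tokens within ``window``."""
    config = config or TrainingConfig()
    sentences = list(sentences)
    if not any(len(s) for s in sentences):
        raise ValueError("empty corpus")
    return train_sgns(window_pairs(sentences, config.window), config)
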