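"""Triplet-sentence CBOW embedding of knowledge-graph entities and relations.

Every triplet ``<h, r, t>`` becomes one three-token sentence
``[head_key, relation_name, tail_key]``; the whole edge set is the corpus.
A continuous bag-of-words (CBOW) word2vec model with negative sampling is
then trained on those sentences, producing one dense vector per entity *and*
per relation token. With ``window=2`` the context always spans the full
sentence, so each entity is predicted from its relation plus partner entity —
the only co-occurrence signal a triplet carries.

The trainer is a self-contained numpy implementation of CBOW with
negative sampling (unigram^0.75 noise distribution, linearly decayed learning
rate). It is sequential and fully seeded, so a (corpus, config) pair maps to
exactly one embedding table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .kg import KnowledgeGraph

__all__ = [
    "Corpus",
    "EmbeddingConfig",
    "EmbeddingTable",
    "OOVError",
    "triplets_to_corpus",
    "train_cbow",
]


class OOVError(KeyError):
    """Lookup of a token that has no trained vector."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"token {token!r} is out of vocabulary")


@dataclass(frozen=True)
class Corpus:
    """Ordered triplet sentences; each sentence is exactly three tokens."""

    sentences: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.sentences)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for sent in self.sentences:
                fh.write(" ".join(sent) + "\n")

    @classmethod
    def load(cls, path) -> "Corpus":
        with open(path, encoding="utf-8") as fh:
            return cls(tuple(tuple(line.split()) for line in fh if line.strip()))


@dataclass(frozen=True)
class EmbeddingConfig:
    """CBOW hyperparameters.

    ``vector_size`` follows the reference grid-searched value of 1024; tests
    and desk-scale runs override it downward. ``window=2`` guarantees the
    context covers a whole 3-token sentence from any position. ``min_count=1``
    keeps every drug/disease in the vocabulary.
    """

    vector_size: int = 1024
    window: int = 2
    epochs: int = 50
    min_count: int = 1
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.vector_size <= 0:
            raise ValueError("vector_size must be positive")
        if self.min_count < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("window, epochs and min_count must be >= 1")

    def replace(self, **kw) -> "EmbeddingConfig":
        return replace(self, **kw)


class EmbeddingTable:
    """Token → dense vector map for every embedded entity and relation."""

    def __init__(self, tokens: Sequence[str], vectors: np.ndarray,
                 config: EmbeddingConfig):
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(tokens):
            raise ValueError("vectors must be (n_tokens, vector_size)")
        self.tokens = list(tokens)
        self.vectors = vectors
        self.config = config
        self._index = {tok: i for i, tok in enumerate(self.tokens)}

    @property
    def vector_size(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def lookup(self, token: str) -> np.ndarray:
        """Return the vector for ``token`` (a copy; the table is immutable)."""
        try:
            return self.vectors[self._index[token]].copy()
        except KeyError:
            raise OOVError(token) from None

    def lookup_many(self, tokens: Iterable[str]) -> np.ndarray:
        idx = []
        for tok in tokens:
            if tok not in self._index:
                raise OOVError(tok)
            idx.append(self._index[tok])
        return self.vectors[idx].copy()

    def save(self, path) -> None:
        """Persist in word2vec text format (header line, then token + floats)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.tokens)} {self.vector_size}\n")
            for tok, vec in zip(self.tokens, self.vectors):
                fh.write(tok + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path, config: EmbeddingConfig | None = None) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            tokens, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(tokens) != n:
            raise ValueError("corrupt embedding file: token count mismatch")
        cfg = config or EmbeddingConfig(vector_size=dim)
        return cls(tokens, np.asarray(rows), cfg)


def triplets_to_corpus(kg: KnowledgeGraph, seed: int = 0) -> Corpus:
    """Serialize every triplet as a 3-token sentence in seeded shuffled order."""
    if not kg.triplets:
        raise ValueError("cannot build a corpus from an empty graph")
    sentences = [(t.head, t.relation.value, t.tail) for t in sorted(kg.triplets)]
    rng = np.random.default_rng(seed)
    rng.shuffle(sentences)
    return Corpus(tuple(sentences))


def train_cbow(corpus: Corpus, config: EmbeddingConfig) -> EmbeddingTable:
    """Train CBOW-with-negative-sampling vectors on the triplet corpus.

    Deterministic for a fixed ``config.seed``: initialization, per-epoch
    sentence order and noise draws all come from one seeded generator and
    updates are applied sequentially.
    """
    if not corpus.sentences:
        raise ValueError("corpus is empty")

    counts = Counter(tok for sent in corpus.sentences for tok in sent)
    if any(not tok for tok in counts):
        raise ValueError("corpus contains empty tokens")
    vocab = [tok for tok, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
             if c >= config.min_count]
    if not vocab:
        raise ValueError("min_count leaves an empty vocabulary")
    index = {tok: i for i, tok in enumerate(vocab)}

    dim = config.vector_size
    rng = np.random.default_rng(config.seed)
    w_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    w_out = np.zeros((len(vocab), dim))

    # Unigram^0.75 noise distribution over the kept vocabulary.
    noise = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    sents = [np.array([index[t] for t in sent if t in index], dtype=np.intp)
             for sent in corpus.sentences]
    sents = [s for s in sents if len(s) >= 2]
    if not sents:
        raise ValueError("no trainable sentences after min_count filtering")

    total_steps = config.epochs * sum(len(s) for s in sents)
    span = config.alpha - config.min_alpha
    step = 0
    for _ in range(config.epochs):
        for si in rng.permutation(len(sents)):
            sent = sents[si]
            for pos, center in enumerate(sent):
                step += 1
                lo = max(0, pos - config.window)
                ctx = np.concatenate(
                    (sent[lo:pos], sent[pos + 1: pos + 1 + config.window]))
                if ctx.size == 0:
                    continue
                lr = config.min_alpha + span * (1.0 - step / total_steps)
                h = w_in[ctx].mean(axis=0)
                negs = np.searchsorted(noise_cdf, rng.random(config.negative))
                targets = np.concatenate(([center], negs))
                labels = np.zeros(targets.size)
                labels[0] = 1.0
                scores = 1.0 / (1.0 + np.exp(-(w_out[targets] @ h)))
                g = (scores - labels) * lr
                grad_h = g @ w_out[targets]
                np.subtract.at(w_out, targets, np.outer(g, h))
                np.subtract.at(w_in, ctx,
                               np.broadcast_to(grad_h / ctx.size, (ctx.size, dim)))
    return EmbeddingTable(vocab, w_in, config)
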