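"""Tokenisation, word embeddings, and seed-lexicon expansion.

The domain lexicons are built in three steps: tokenize the post stream (a
pluggable splitter, whitespace by default, so a Chinese segmenter can be
dropped in for real data), train word embeddings on the tokenised corpus,
and expand each seed-word list to every vocabulary word whose cosine
similarity to a seed exceeds a threshold (0.3260 for problem lexicons and
0.3556 for influential-factor lexicons by default).

Embeddings are count-based: a symmetric-window co-occurrence matrix is
reweighted by positive pointwise mutual information (PPMI) and factored by a
truncated SVD, giving dense vectors whose cosine geometry reflects
co-occurrence — the same similarity structure a skip-gram model targets,
but exactly reproducible and fast on small corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .synthetic import PostRecord

__all__ = [
    "TokenizedCorpus",
    "EmbeddingConfig",
    "EmbeddingModel",
    "Lexicon",
    "SeedCoverageError",
    "tokenize_posts",
    "train_word_embeddings",
    "cosine_similarity",
    "expand_lexicon",
]

PROBLEMS_THRESHOLD = 0.3260
FACTORS_THRESHOLD = 0.3556


class SeedCoverageError(KeyError):
    """Raised when none of a lexicon's seed words is in the vocabulary."""


@dataclass(frozen=True)
class TokenizedCorpus:
    """Token lists per post, in post order, with the stopwords that were removed."""

    documents: tuple[tuple[int, tuple[str, ...]], ...]
    stopwords_applied: frozenset[str] = frozenset()

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(doc_id for doc_id, _ in self.documents)

    @property
    def empty_ids(self) -> tuple[int, ...]:
        return tuple(doc_id for doc_id, tokens in self.documents if not tokens)

    def token_iter(self) -> Iterable[str]:
        for _, tokens in self.documents:
            yield from tokens


def tokenize_posts(
    posts: Sequence[PostRecord],
    stopword_list: Iterable[str] = (),
    tokenizer: Callable[[str], list[str]] | None = None,
) -> TokenizedCorpus:
    """Split each post into tokens and drop stopwords, preserving post order.

    ``tokenizer`` defaults to whitespace splitting; pass a segmenter callable
    for languages without whitespace word boundaries.  Empty token lists are
    permitted (such posts are dropped downstream, not here).
    """
    if len(posts) == 0:
        raise ValueError("posts must be non-empty")
    split = tokenizer or str.split
    stopwords = frozenset(stopword_list)
    documents = tuple(
        (i, tuple(tok for tok in split(post.text) if tok not in stopwords))
        for i, post in enumerate(posts)
    )
    return TokenizedCorpus(documents=documents, stopwords_applied=stopwords)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding hyperparameters: vector size, window, frequency floor, seed.

    ``shift_k`` applies the shifted-PPMI reweighting max(0, PMI - log k),
    the count-based analogue of skip-gram negative sampling with k noise
    samples; it suppresses the upward bias that positive clipping gives to
    rare, noisy co-occurrences while leaving strong topical associations
    intact.
    """

    dim: int = 100
    window: int = 5
    min_count: int = 2
    shift_k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.shift_k < 1:
            raise ValueError("shift_k must be >= 1")


@dataclass(frozen=True)
class EmbeddingModel:
    """A vocabulary and one finite real vector per word."""

    words: tuple[str, ...]
    vectors: np.ndarray
    config: EmbeddingConfig
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.words):
            raise ValueError("one vector per vocabulary word required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        object.__setattr__(
            self, "_index", {w: i for i, w in enumerate(self.words)}
        )

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not in embedding vocabulary") from None

    def similarity(self, a: str, b: str) -> float:
        return cosine_similarity(self.vector(a), self.vector(b))


def train_word_embeddings(
    corpus: TokenizedCorpus,
    config: EmbeddingConfig | None = None,
) -> EmbeddingModel:
    """Train PPMI-SVD word embeddings on the tokenised corpus.

    Co-occurrence is counted in a symmetric window of ``config.window``
    tokens within each document, reweighted by positive PMI, and factored by
    a truncated SVD; word vectors are ``U * sqrt(S)``.  The result is fully
    deterministic (SVD signs are fixed by convention).  Words with corpus
    frequency below ``min_count`` are excluded from the vocabulary.
    """
    config = config or EmbeddingConfig()
    counts: dict[str, int] = {}
    for token in corpus.token_iter():
        counts[token] = counts.get(token, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= config.min_count)
    if not vocab:
        raise ValueError(
            f"no word reaches min_count={config.min_count}; effective vocabulary empty"
        )
    index = {w: i for i, w in enumerate(vocab)}
    n = len(vocab)

    cooc = np.zeros((n, n), dtype=float)
    for _, tokens in corpus.documents:
        idx = [index[t] for t in tokens if t in index]
        for pos, i in enumerate(idx):
            for j in idx[pos + 1 : pos + 1 + config.window]:
                cooc[i, j] += 1.0
                cooc[j, i] += 1.0

    total = cooc.sum()
    if total == 0:
        # Single-word documents only: no co-occurrence signal at all.  Give
        # every word a distinct deterministic random vector.
        rng = np.random.default_rng(config.seed)
        vectors = rng.normal(size=(n, min(config.dim, max(2, n))))
        return EmbeddingModel(words=tuple(vocab), vectors=vectors, config=config)

    row = cooc.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((cooc * total) / (row * row.T)) - np.log(config.shift_k)
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    k = min(config.dim, n)
    # Dense SVD: deterministic; vocabulary sizes here are small (10^2-10^3).
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    u, s = u[:, :k], s[:k]
    # Fix the SVD sign ambiguity: make the largest-|u| entry of each
    # component positive.
    for c in range(k):
        pivot = np.argmax(np.abs(u[:, c]))
        if u[pivot, c] < 0:
            u[:, c] = -u[:, c]
    vectors = u * np.sqrt(s)
    return EmbeddingModel(words=tuple(vocab), vectors=vectors, config=config)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class Lexicon:
    """A seed word list plus its embedding-space expansion.

    ``expanded`` maps every lexicon word to its maximum cosine similarity to
    any seed (seeds carry similarity 1.0); every non-seed word's similarity
    strictly exceeds ``threshold``.  Seeds missing from the embedding
    vocabulary are reported in ``missing_seeds``, never silently dropped.
    """

    name: str
    seeds: tuple[str, ...]
    threshold: float
    expanded: dict[str, float]
    missing_seeds: tuple[str, ...] = ()

    @property
    def words(self) -> frozenset[str]:
        return frozenset(self.expanded)

    def __len__(self) -> int:
        return len(self.expanded)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "threshold": self.threshold,
            "seeds": list(self.seeds),
            "missing_seeds": list(self.missing_seeds),
            "expanded": [
                {"word": w, "similarity": s}
                for w, s in sorted(self.expanded.items())
            ],
        }
        Path(path).write_text(
            json.dumps(payload, sort_keys=True, indent=1), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=payload["name"],
            seeds=tuple(payload["seeds"]),
            threshold=float(payload["threshold"]),
            expanded={e["word"]: float(e["similarity"]) for e in payload["expanded"]},
            missing_seeds=tuple(payload.get("missing_seeds", ())),
        )


def expand_lexicon(
    model: EmbeddingModel,
    seeds: Sequence[str],
    threshold: float,
    name: str = "lexicon",
    aggregate: str = "max",
) -> Lexicon:
    """Expand seed words to all vocabulary words above a similarity cutoff.

    A vocabulary word enters the lexicon when its similarity to the seeds —
    the maximum over seeds by default, the mean with ``aggregate="mean"`` —
    strictly exceeds ``threshold``.  Seeds are always retained regardless of
    the threshold.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [-1, 1], got {threshold}")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    seeds = tuple(dict.fromkeys(seeds))  # de-duplicate, keep order
    in_vocab = [s for s in seeds if s in model]
    missing = tuple(s for s in seeds if s not in model)
    if not in_vocab:
        raise SeedCoverageError(
            f"no seed word of lexicon {name!r} is in the vocabulary; "
            f"missing: {list(missing)}"
        )

    norms = np.linalg.norm(model.vectors, axis=1)
    safe = np.where(norms < 1e-300, 1.0, norms)
    unit = model.vectors / safe[:, None]
    seed_idx = [model._index[s] for s in in_vocab]
    sims = unit @ unit[seed_idx].T  # (n_vocab, n_seeds)
    agg = sims.max(axis=1) if aggregate == "max" else sims.mean(axis=1)

    expanded = {
        model.words[i]: float(agg[i])
        for i in np.flatnonzero(agg > threshold)
        if model.words[i] not in seeds
    }
    for seed in seeds:
        expanded[seed] = 1.0
    return Lexicon(
        name=name,
        seeds=seeds,
        threshold=float(threshold),
        expanded=expanded,
        missing_seeds=missing,
    )
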