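"""Topic detection over lexicon-filtered posts.

Posts are reduced to their in-lexicon tokens, embedded as the average of
their word vectors, and clustered with k-means; the number of clusters is
chosen by scanning k over a range (4-20 by default) and keeping the k with
the highest silhouette coefficient, ties broken toward the smaller k.  Each
cluster is a topic; its daily post counts become the topic-frequency
predictors, and its most frequent in-lexicon words label it.

The problem and factor semantics are clustered separately (one run per
lexicon) so the two families do not interfere; the pipeline concatenates the
two topic-frequency blocks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .lexicon import EmbeddingModel, Lexicon, TokenizedCorpus
from .synthetic import PostRecord

__all__ = [
    "DocumentVectorSet",
    "ClusteringResult",
    "TopicFrequencySeries",
    "filter_by_lexicon",
    "average_embed",
    "silhouette",
    "cluster_topics",
    "daily_topic_frequencies",
]


def filter_by_lexicon(corpus: TokenizedCorpus, lexicon: Lexicon) -> TokenizedCorpus:
    """Keep only in-lexicon tokens in every document.

    Documents emptied by the filter stay in the corpus (flagged via
    ``TokenizedCorpus.empty_ids``) so downstream stages can drop them
    explicitly.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    words = lexicon.words
    documents = tuple(
        (doc_id, tuple(tok for tok in tokens if tok in words))
        for doc_id, tokens in corpus.documents
    )
    return TokenizedCorpus(documents=documents, stopwords_applied=corpus.stopwords_applied)


@dataclass(frozen=True)
class DocumentVectorSet:
    """Average-word-embedding document vectors plus the posts that had none."""

    ids: tuple[int, ...]
    vectors: np.ndarray
    dropped_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("one vector per kept document required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("document vectors must be finite")


def average_embed(corpus: TokenizedCorpus, model: EmbeddingModel) -> DocumentVectorSet:
    """Embed each document as the arithmetic mean of its in-vocabulary vectors.

    Documents with no covered token are reported in ``dropped_ids``; if every
    document is dropped an error is raised.
    """
    kept_ids: list[int] = []
    dropped: list[int] = []
    rows: list[np.ndarray] = []
    for doc_id, tokens in corpus.documents:
        vecs = [model.vector(t) for t in tokens if t in model]
        if vecs:
            kept_ids.append(doc_id)
            rows.append(np.mean(vecs, axis=0))
        else:
            dropped.append(doc_id)
    if not rows:
        raise ValueError("embedding model covers no token of any document")
    return DocumentVectorSet(
        ids=tuple(kept_ids),
        vectors=np.vstack(rows),
        dropped_ids=tuple(dropped),
    )


def silhouette(vectors: DocumentVectorSet | np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient, Euclidean metric, in [-1, 1].

    For each point, a is its mean distance to its own cluster's other
    members and b the smallest mean distance to another cluster; the point's
    score is (b - a) / max(a, b).
    """
    array = vectors.vectors if isinstance(vectors, DocumentVectorSet) else np.asarray(vectors)
    labels = np.asarray(labels)
    if array.shape[0] != labels.shape[0]:
        raise ValueError("one label per document required")
    if array.shape[0] < 3:
        raise ValueError("silhouette requires at least 3 documents")
    if np.unique(labels).size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(array, labels, metric="euclidean"))


@dataclass(frozen=True)
class ClusteringResult:
    """The silhouette-selected k-means model plus the full silhouette scan."""

    k: int
    labels: np.ndarray
    centers: np.ndarray
    silhouette: float
    per_k_silhouettes: dict[int, float]

    def __post_init__(self) -> None:
        if self.labels.max(initial=-1) >= self.k:
            raise ValueError("cluster label out of range")
        if abs(self.per_k_silhouettes[self.k] - self.silhouette) > 1e-12:
            raise ValueError("selected silhouette disagrees with the scan")


def cluster_topics(
    vectors: DocumentVectorSet | np.ndarray,
    k_range: Iterable[int] = range(4, 21),
    seed: int = 0,
    n_init: int = 10,
    silhouette_sample_size: int | None = 5000,
) -> ClusteringResult:
    """k-means over a scan of cluster counts; keep the best-silhouette k.

    k-means++ initialisation with ``n_init`` restarts and a fixed seed per
    candidate k; ties in silhouette break toward the smaller k (parsimony).
    On corpora larger than ``silhouette_sample_size`` documents the
    silhouette of each candidate k is evaluated on a seeded subsample of
    that size (silhouette is quadratic in the document count; pass ``None``
    to force the exact computation).
    """
    array = vectors.vectors if isinstance(vectors, DocumentVectorSet) else np.asarray(vectors)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ValueError("k_range must contain integers >= 2")
    if array.shape[0] <= max(ks):
        raise ValueError(
            f"document count {array.shape[0]} must exceed max k {max(ks)}"
        )
    sample_size = silhouette_sample_size
    if sample_size is not None and array.shape[0] <= sample_size:
        sample_size = None

    scan: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
        labels = km.fit_predict(array)
        if np.unique(labels).size < 2:
            scan[k] = -1.0
        else:
            scan[k] = float(
                silhouette_score(
                    array,
                    labels,
                    metric="euclidean",
                    sample_size=sample_size,
                    random_state=seed,
                )
            )
        fits[k] = km
    best_k = max(ks, key=lambda k: (scan[k], -k))
    best = fits[best_k]
    return ClusteringResult(
        k=best_k,
        labels=best.labels_.astype(int),
        centers=best.cluster_centers_,
        silhouette=scan[best_k],
        per_k_silhouettes=scan,
    )


@dataclass(frozen=True)
class TopicFrequencySeries:
    """Daily post counts per topic plus each topic's high-frequency keywords."""

    frequencies: pd.DataFrame
    keywords: dict[int, tuple[str, ...]]

    @property
    def topics(self) -> tuple[str, ...]:
        return tuple(self.frequencies.columns)


def daily_topic_frequencies(
    posts: Sequence[PostRecord],
    labels: Sequence[int],
    calendar: pd.DatetimeIndex,
    filtered_corpus: TokenizedCorpus | None = None,
    top_n: int = 10,
    prefix: str = "topic",
) -> TopicFrequencySeries:
    """Count posts per (day, cluster); days without posts get zero rows.

    ``posts`` and ``labels`` must be aligned (the clustered subset, in
    order).  When ``filtered_corpus`` is supplied its documents must align
    the same way and the per-cluster ``top_n`` most frequent in-lexicon
    words are reported as topic keywords.
    """
    labels = np.asarray(labels, dtype=int)
    if len(posts) != labels.shape[0]:
        raise ValueError("labels must align one-to-one with posts")
    k = int(labels.max()) + 1 if labels.size else 0
    columns = [f"{prefix}_{c}" for c in range(k)]
    counts = pd.DataFrame(0, index=calendar, columns=columns, dtype=int)
    cal_days = set(calendar.date)
    for post, label in zip(posts, labels):
        if post.date not in cal_days:
            raise ValueError(f"post dated {post.date} outside the calendar")
        counts.loc[pd.Timestamp(post.date), f"{prefix}_{label}"] += 1

    keywords: dict[int, tuple[str, ...]] = {}
    if filtered_corpus is not None:
        if len(filtered_corpus.documents) != labels.shape[0]:
            raise ValueError("filtered corpus must align one-to-one with labels")
        per_cluster: dict[int, Counter] = {c: Counter() for c in range(k)}
        for (_, tokens), label in zip(filtered_corpus.documents, labels):
            per_cluster[int(label)].update(tokens)
        for c in range(k):
            ranked = sorted(per_cluster[c].items(), key=lambda kv: (-kv[1], kv[0]))
            keywords[c] = tuple(w for w, _ in ranked[:top_n])
    return TopicFrequencySeries(frequencies=counts, keywords=keywords)
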