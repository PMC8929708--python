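"""End-to-end feature pipeline: posts + epidemic table -> predictor bundle.

Glues the stages together the way the analysis runs them: tokenize the post
stream, train embeddings, expand the problem and factor seed lexicons at
their respective thresholds (0.3260 / 0.3556), run topic detection once per
lexicon and concatenate the two topic-frequency blocks, compute the
dictionary-category linguistic features, fit the additive decomposition of
the primary count series, and assemble everything into a
:class:`~ophs.forecasting.FeatureBundle` aligned on the daily calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .forecasting import FeatureBundle
from .lexicon import (
    FACTORS_THRESHOLD,
    PROBLEMS_THRESHOLD,
    EmbeddingConfig,
    EmbeddingModel,
    Lexicon,
    TokenizedCorpus,
    expand_lexicon,
    tokenize_posts,
    train_word_embeddings,
)
from .liwc import CategoryDictionary, daily_category_features, default_category_dictionary
from .synthetic import PostRecord
from .temporal import DecompositionConfig, extract_temporal_features, fit_decomposition
from .topics import (
    ClusteringResult,
    TopicFrequencySeries,
    average_embed,
    cluster_topics,
    daily_topic_frequencies,
    filter_by_lexicon,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_feature_pipeline", "detect_topics"]


@dataclass(frozen=True)
class PipelineConfig:
    """Stage configuration for the full feature pipeline."""

    problems_threshold: float = PROBLEMS_THRESHOLD
    factors_threshold: float = FACTORS_THRESHOLD
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    k_range: tuple[int, int] = (4, 20)
    kmeans_n_init: int = 10
    silhouette_sample_size: int | None = 5000
    top_n_keywords: int = 10
    stopwords: tuple[str, ...] = ()
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)


@dataclass(frozen=True)
class TopicRun:
    """One lexicon's topic-detection outputs."""

    lexicon: Lexicon
    clustering: ClusteringResult
    frequencies: TopicFrequencySeries
    kept_post_indices: tuple[int, ...]


def detect_topics(
    posts: Sequence[PostRecord],
    corpus: TokenizedCorpus,
    model: EmbeddingModel,
    lexicon: Lexicon,
    calendar: pd.DatetimeIndex,
    config: PipelineConfig,
    seed: int,
) -> TopicRun:
    """Filter -> average-embed -> cluster -> daily frequencies for one lexicon."""
    filtered = filter_by_lexicon(corpus, lexicon)
    kept_docs = tuple(
        (doc_id, tokens) for doc_id, tokens in filtered.documents if tokens
    )
    kept = TokenizedCorpus(documents=kept_docs, stopwords_applied=filtered.stopwords_applied)
    vectors = average_embed(kept, model)
    clustering = cluster_topics(
        vectors,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        seed=seed,
        n_init=config.kmeans_n_init,
        silhouette_sample_size=config.silhouette_sample_size,
    )
    kept_posts = [posts[i] for i in vectors.ids]
    frequencies = daily_topic_frequencies(
        kept_posts,
        clustering.labels,
        calendar,
        filtered_corpus=TokenizedCorpus(
            documents=tuple(
                doc for doc in kept_docs if doc[0] in set(vectors.ids)
            ),
            stopwords_applied=filtered.stopwords_applied,
        ),
        top_n=config.top_n_keywords,
        prefix=lexicon.name,
    )
    return TopicRun(
        lexicon=lexicon,
        clustering=clustering,
        frequencies=frequencies,
        kept_post_indices=vectors.ids,
    )


@dataclass(frozen=True)
class PipelineResult:
    """The predictor bundle plus every intermediate artifact."""

    bundle: FeatureBundle
    embedding: EmbeddingModel
    problems: TopicRun
    factors: TopicRun
    liwc_features: pd.DataFrame
    temporal_features: pd.DataFrame


def run_feature_pipeline(
    posts: Sequence[PostRecord],
    epidemic: pd.DataFrame,
    counts_primary: pd.Series,
    problem_seeds: Sequence[str],
    factor_seeds: Sequence[str],
    config: PipelineConfig | None = None,
    dictionary: CategoryDictionary | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Build the four predictor blocks from the raw inputs.

    The embedding is trained once on the full tokenised corpus; the problem
    and factor lexicons are expanded from it at their own thresholds, and
    topic detection runs once per lexicon so the two semantic families do
    not interfere.  The returned bundle's blocks are ``liwc``, ``topic``
    (both lexicons' frequency columns), ``temporal``, and ``covid``.
    """
    config = config or PipelineConfig()
    dictionary = dictionary or default_category_dictionary()
    calendar = pd.DatetimeIndex(counts_primary.index)

    corpus = tokenize_posts(posts, stopword_list=config.stopwords)
    embedding = train_word_embeddings(corpus, config.embedding)

    problems_lexicon = expand_lexicon(
        embedding, problem_seeds, config.problems_threshold, name="problems"
    )
    factors_lexicon = expand_lexicon(
        embedding, factor_seeds, config.factors_threshold, name="factors"
    )

    problems = detect_topics(
        posts, corpus, embedding, problems_lexicon, calendar, config, seed
    )
    factors = detect_topics(
        posts, corpus, embedding, factors_lexicon, calendar, config, seed
    )
    topic_block = pd.concat(
        [problems.frequencies.frequencies, factors.frequencies.frequencies], axis=1
    )

    liwc_block = daily_category_features(posts, dictionary, calendar)

    decomposition = fit_decomposition(
        counts_primary.reindex(calendar).fillna(0.0), config.decomposition
    )
    temporal_block = extract_temporal_features(decomposition, calendar)

    covid_block = epidemic.reindex(calendar).fillna(0.0)

    bundle = FeatureBundle(
        blocks={
            "liwc": liwc_block,
            "topic": topic_block,
            "temporal": temporal_block,
            "covid": covid_block,
        }
    )
    return PipelineResult(
        bundle=bundle,
        embedding=embedding,
        problems=problems,
        factors=factors,
        liwc_features=liwc_block,
        temporal_features=temporal_block,
    )
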