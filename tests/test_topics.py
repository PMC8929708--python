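"""Lexicon filtering, document embedding, clustering, and topic frequencies."""

import datetime
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import ophs
from ophs.lexicon import TokenizedCorpus
from ophs.topics import DocumentVectorSet


def _lexicon(words, name="test"):
    return ophs.Lexicon(
        name=name,
        seeds=tuple(words[:1]),
        threshold=0.0,
        expanded={w: 1.0 for w in words},
    )


def _corpus(token_lists):
    return TokenizedCorpus(
        documents=tuple((i, tuple(toks)) for i, toks in enumerate(token_lists))
    )


class TestFilterByLexicon:
    def test_full_lexicon_is_identity(self):
        corpus = _corpus([["a", "b"], ["c"]])
        out = ophs.filter_by_lexicon(corpus, _lexicon(["a", "b", "c"]))
        assert out.documents == corpus.documents

    def test_disjoint_lexicon_empties_and_flags(self):
        corpus = _corpus([["a", "b"], ["c"]])
        out = ophs.filter_by_lexicon(corpus, _lexicon(["z"]))
        assert all(not toks for _, toks in out.documents)
        assert out.empty_ids == (0, 1)

    def test_planted_corpus_keeps_exactly_topical_words(self, problem_specs):
        """With generic words removed up front (the stop-word step of the
        pipeline), the lexicon filter keeps exactly the planted seed and
        satellite words; without that step, all planted words still survive
        and only a handful of marginal background words slip through."""
        from ophs.synthetic import default_background_vocab

        counts = pd.Series(
            40, index=pd.date_range("2020-01-31", periods=60, name="date")
        )
        posts = ophs.generate_post_corpus(counts, problem_specs, seed=17)
        seeds = [w for spec in problem_specs for w in spec.seed_words]
        truth = {
            w for spec in problem_specs for w in spec.seed_words + spec.satellite_words
        }

        stopped = ophs.tokenize_posts(posts, stopword_list=default_background_vocab())
        model = ophs.train_word_embeddings(stopped, ophs.EmbeddingConfig(dim=50))
        lexicon = ophs.expand_lexicon(model, seeds, 0.3260, name="problems")
        surviving = set(ophs.filter_by_lexicon(stopped, lexicon).token_iter())
        assert surviving == truth

        raw = ophs.tokenize_posts(posts)
        model_raw = ophs.train_word_embeddings(raw, ophs.EmbeddingConfig(dim=50))
        lexicon_raw = ophs.expand_lexicon(model_raw, seeds, 0.3260, name="problems")
        surviving_raw = set(ophs.filter_by_lexicon(raw, lexicon_raw).token_iter())
        assert truth <= surviving_raw
        assert len(surviving_raw - truth) <= 5  # marginal background neighbours


class TestAverageEmbed:
    @pytest.fixture()
    def toy_model(self):
        return ophs.EmbeddingModel(
            words=("u", "v", "w"),
            vectors=np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]]),
            config=ophs.EmbeddingConfig(dim=2, min_count=1),
        )

    def test_single_token_equals_word_vector(self, toy_model):
        out = ophs.average_embed(_corpus([["u"]]), toy_model)
        np.testing.assert_array_equal(out.vectors[0], [1.0, 0.0])

    def test_two_tokens_mean(self, toy_model):
        out = ophs.average_embed(_corpus([["u", "v"]]), toy_model)
        np.testing.assert_allclose(out.vectors[0], [0.5, 1.0])

    def test_duplicate_documents_identical(self, toy_model):
        out = ophs.average_embed(_corpus([["u", "w"], ["u", "w"]]), toy_model)
        np.testing.assert_array_equal(out.vectors[0], out.vectors[1])

    def test_token_order_invariance(self, toy_model):
        a = ophs.average_embed(_corpus([["u", "v", "w"]]), toy_model)
        b = ophs.average_embed(_corpus([["w", "u", "v"]]), toy_model)
        np.testing.assert_allclose(a.vectors, b.vectors)

    def test_uncovered_documents_dropped(self, toy_model):
        out = ophs.average_embed(_corpus([["u"], ["zzz"]]), toy_model)
        assert out.ids == (0,) and out.dropped_ids == (1,)

    def test_all_dropped_errors(self, toy_model):
        with pytest.raises(ValueError):
            ophs.average_embed(_corpus([["zzz"]]), toy_model)


def _brute_silhouette(points, labels):
    """Direct (b - a) / max(a, b) evaluation, averaged over points."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    scores = []
    for i in range(len(points)):
        own = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in own])
        b = min(
            np.mean(
                [
                    np.linalg.norm(points[i] - points[j])
                    for j in range(len(points))
                    if labels[j] == other
                ]
            )
            for other in set(labels) - {labels[i]}
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestSilhouette:
    def test_separated_clusters_near_one(self):
        pts = np.array([[0, 0], [0, 0.01], [10, 10], [10, 10.01]])
        assert ophs.silhouette(pts, [0, 0, 1, 1]) > 0.99

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_four_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 2))
        labels = [0, 0, 1, 1]
        assert ophs.silhouette(pts, labels) == pytest.approx(
            _brute_silhouette(pts, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_range(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 3))
        labels = rng.integers(0, 3, size=12)
        if np.unique(labels).size < 2:
            return
        assert -1.0 <= ophs.silhouette(pts, labels) <= 1.0

    def test_single_cluster_error(self):
        with pytest.raises(ValueError, match="single cluster"):
            ophs.silhouette(np.eye(4), [0, 0, 0, 0])


def _blobs(k, per=30, dim=8, spread=8.0, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=spread, size=(k, dim))
    points = np.vstack(
        [center + rng.normal(scale=noise, size=(per, dim)) for center in centers]
    )
    labels = np.repeat(np.arange(k), per)
    return points, labels


class TestClusterTopics:
    def test_planted_k_recovered(self):
        points, _ = _blobs(7, seed=1)
        result = ophs.cluster_topics(points, k_range=range(4, 21), seed=0)
        assert result.k == 7
        assert result.silhouette == max(result.per_k_silhouettes.values())

    def test_two_blob_partition(self):
        points, truth = _blobs(2, per=10, seed=2)
        result = ophs.cluster_topics(points, k_range=[2], seed=0)
        # labels partition exactly by blob (up to label permutation)
        mapping = {}
        for label, true in zip(result.labels, truth):
            mapping.setdefault(label, true)
            assert mapping[label] == true

    def test_deterministic(self):
        points, _ = _blobs(4, per=15, seed=3)
        a = ophs.cluster_topics(points, k_range=range(4, 8), seed=9)
        b = ophs.cluster_topics(points, k_range=range(4, 8), seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_k_exceeding_documents_errors(self):
        points, _ = _blobs(2, per=3, seed=4)
        with pytest.raises(ValueError, match="exceed"):
            ophs.cluster_topics(points, k_range=range(4, 21), seed=0)


class TestDailyTopicFrequencies:
    def _posts(self, dates):
        return [
            ophs.PostRecord(date=d, text="tok") for d in dates
        ]

    def test_single_cell(self):
        calendar = pd.date_range("2020-02-01", periods=3, name="date")
        posts = self._posts([datetime.date(2020, 2, 2)] * 4)
        out = ophs.daily_topic_frequencies(posts, [0, 0, 0, 0], calendar)
        assert out.frequencies.loc["2020-02-02", "topic_0"] == 4
        assert out.frequencies.to_numpy().sum() == 4

    def test_row_sums_conserve_daily_counts(self, demand_small, posts_small,
                                            corpus_small, problems_lexicon,
                                            embedding_small):
        filtered = ophs.filter_by_lexicon(corpus_small, problems_lexicon)
        kept_docs = tuple(d for d in filtered.documents if d[1])
        kept = TokenizedCorpus(documents=kept_docs)
        vectors = ophs.average_embed(kept, embedding_small)
        result = ophs.cluster_topics(vectors, k_range=[7], seed=0, n_init=3)
        kept_posts = [posts_small[i] for i in vectors.ids]
        calendar = pd.DatetimeIndex(demand_small.primary.index)
        out = ophs.daily_topic_frequencies(kept_posts, result.labels, calendar)
        per_day = Counter(pd.Timestamp(p.date) for p in kept_posts)
        rows = out.frequencies.sum(axis=1)
        for day, total in per_day.items():
            assert rows.loc[day] == total
        assert int(out.frequencies.to_numpy().sum()) == len(kept_posts)

    def test_cluster_purity_against_truth(self, posts_small, corpus_small,
                                          problems_lexicon, embedding_small):
        """Majority true-topic purity of the recovered clusters is high."""
        filtered = ophs.filter_by_lexicon(corpus_small, problems_lexicon)
        kept_docs = tuple(d for d in filtered.documents if d[1])
        kept = TokenizedCorpus(documents=kept_docs)
        vectors = ophs.average_embed(kept, embedding_small)
        result = ophs.cluster_topics(vectors, k_range=[7], seed=0, n_init=3)
        kept_posts = [posts_small[i] for i in vectors.ids]
        purities = []
        for c in range(result.k):
            members = [
                p.true_topic for p, l in zip(kept_posts, result.labels) if l == c
            ]
            if members:
                purities.append(Counter(members).most_common(1)[0][1] / len(members))
        assert np.mean(purities) >= 0.8

    def test_post_outside_calendar_errors(self):
        calendar = pd.date_range("2020-02-01", periods=2, name="date")
        posts = self._posts([datetime.date(2020, 3, 1)])
        with pytest.raises(ValueError, match="outside"):
            ophs.daily_topic_frequencies(posts, [0], calendar)

    def test_keyword_table(self):
        calendar = pd.date_range("2020-02-01", periods=1, name="date")
        posts = [
            ophs.PostRecord(date=datetime.date(2020, 2, 1), text="a a b"),
            ophs.PostRecord(date=datetime.date(2020, 2, 1), text="c"),
        ]
        corpus = _corpus([["a", "a", "b"], ["c"]])
        out = ophs.daily_topic_frequencies(
            posts, [0, 1], calendar, filtered_corpus=corpus, top_n=2
        )
        assert out.keywords[0] == ("a", "b")
        assert out.keywords[1] == ("c",)
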