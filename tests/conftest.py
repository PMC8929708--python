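"""Shared fixtures: a small synthetic study generated once per session."""

import numpy as np
import pandas as pd
import pytest

import ophs
from ophs import synthetic as syn


@pytest.fixture(scope="session")
def epidemic_small() -> pd.DataFrame:
    return ophs.generate_epidemic_series(
        120, logistic_params=(50_000, 40, 0.15), death_fraction=0.04, seed=11
    )


@pytest.fixture(scope="session")
def demand_small(epidemic_small) -> syn.SyntheticDemand:
    return ophs.generate_ophs_series(120, epidemic_small)


@pytest.fixture(scope="session")
def problem_specs() -> list[syn.TopicSpec]:
    return ophs.default_topic_specs("problems")


@pytest.fixture(scope="session")
def factor_specs() -> list[syn.TopicSpec]:
    return ophs.default_topic_specs("factors")


@pytest.fixture(scope="session")
def posts_small(demand_small, problem_specs, factor_specs) -> list[syn.PostRecord]:
    # Thin the daily counts so text-stage tests stay fast.
    counts = (demand_small.primary // 4).clip(lower=1)
    return ophs.generate_post_corpus(
        counts, problem_specs, seed=7, companion_topics=factor_specs
    )


@pytest.fixture(scope="session")
def corpus_small(posts_small) -> ophs.TokenizedCorpus:
    return ophs.tokenize_posts(posts_small)


@pytest.fixture(scope="session")
def embedding_small(corpus_small) -> ophs.EmbeddingModel:
    return ophs.train_word_embeddings(
        corpus_small, ophs.EmbeddingConfig(dim=50, window=5, min_count=2, seed=0)
    )


@pytest.fixture(scope="session")
def problems_lexicon(embedding_small, problem_specs) -> ophs.Lexicon:
    seeds = [w for spec in problem_specs for w in spec.seed_words]
    return ophs.expand_lexicon(embedding_small, seeds, 0.3260, name="problems")


@pytest.fixture(scope="session")
def temporal_features(demand_small) -> pd.DataFrame:
    model = ophs.fit_decomposition(demand_small.primary)
    return ophs.extract_temporal_features(model)


@pytest.fixture(scope="session")
def bundle_small(epidemic_small, demand_small, temporal_features) -> ophs.FeatureBundle:
    """A two-block bundle (temporal + covid); text blocks are tested separately."""
    return ophs.FeatureBundle(
        blocks={
            "temporal": temporal_features,
            "covid": epidemic_small.astype(float),
        }
    )


@pytest.fixture(scope="session")
def rf_results_p4(epidemic_small, demand_small) -> ophs.DemandModelResults:
    """An RF fit on the four epidemic covariates only (P=4, exact SHAP feasible)."""
    bundle = ophs.FeatureBundle(blocks={"covid": epidemic_small.astype(float)})
    dataset = ophs.build_lagged_dataset(
        bundle, demand_small.primary.astype(float), horizon=3
    )
    model = ophs.DemandModel(
        dataset, algorithm="rf", config=ophs.ModelConfig(rf_n_estimators=100)
    )
    return model.fit(seed=0)
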