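import pytest

import vacoder as vc


@pytest.fixture(scope="session")
def stopwords():
    return vc.StopwordList.default()


@pytest.fixture(scope="session")
def lexicon():
    return vc.Lexicon.default()


@pytest.fixture(scope="session")
def separable_config():
    """Zero-noise generator config with pairwise-disjoint symptom lexicons.

    Under this construction the gold category is recoverable from the
    narrative by vocabulary alone, so classifiers should approach perfect
    individual- and population-level scores.
    """
    scheme = vc.default_scheme()
    lexicons = vc.disjoint_lexicons(
        scheme.categories("adult"), words_per_category=8, seed=11
    )
    return vc.GeneratorConfig(
        scheme=scheme,
        csmf_by_age_group={"adult": vc.synth.SKEWED_CSMF_15},
        n_per_age_group={"adult": 2000},
        category_lexicons=lexicons,
        background_weight=0.0,
        misspelling_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def separable_corpus(separable_config):
    return vc.generate_corpus(separable_config)


def make_toy_matrix(docs_tokens, age_groups, record_ids=None):
    """FeatureMatrix from raw token lists (helper shared across test modules)."""
    ids = record_ids or [f"r{i}" for i in range(len(docs_tokens))]
    docs = [
        vc.TokenizedNarrative(record_id=i, tokens=list(t))
        for i, t in zip(ids, docs_tokens)
    ]
    vocab = vc.build_vocabulary(docs)
    return vc.build_feature_matrix(docs, vocab, age_groups), vocab, docs
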