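"""Shared fixtures: schema, synthetic corpora, and one trained extractor.

The expensive fixtures are session-scoped: the learning-curve run (which
trains the miniature encoder at three training-set sizes on one corpus)
feeds both the parameter-recovery and the curve-shape checks.
"""

from __future__ import annotations

import pytest

from cmrextract import default_schema
from cmrextract.pipeline import learning_curve_run
from cmrextract.synthetic import CorpusConfig, generate_corpus

TRAIN_SEED = 0
TEST_SEED = 1_000_003


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_corpus(schema):
    """30 reports with gold annotations for fast plumbing tests."""
    return generate_corpus(CorpusConfig(n_reports=30, seed=7), schema)


@pytest.fixture(scope="session")
def midsize_corpus(schema):
    """100 reports: the gold-pass-through reference corpus."""
    return generate_corpus(CorpusConfig(n_reports=100, seed=11), schema)


@pytest.fixture(scope="session")
def train_test_corpora(schema):
    train = generate_corpus(CorpusConfig(n_reports=200, seed=TRAIN_SEED), schema)
    test = generate_corpus(CorpusConfig(n_reports=100, seed=TEST_SEED), schema)
    return train, test


@pytest.fixture(scope="session")
def learning_curve_results(train_test_corpora):
    """Macro-F1 at nested training sizes 25/100/200 against a fixed test set.

    One training run per size with the default miniature-encoder recipe;
    the size-200 point doubles as the full parameter-recovery model.
    """
    (train_r, train_a), (test_r, test_a) = train_test_corpora
    return learning_curve_run(
        train_r, train_a, test_r, test_a, sizes=[25, 100, 200], seed=TRAIN_SEED
    )
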