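"""Shared fixtures: synthetic dictionaries, corpora, and one trained model.

Everything is generated at test time from seeds; no data files ship with
the tests.  The trained model fixture is session-scoped because training,
while only ~10 s, is the most expensive step and several tests share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from metanner.dictionary import MetaboliteDictionary, default_stopwords
from metanner.embeddings import WordVectorEmbedder
from metanner.ner import ModelConfig, build_model, encode_corpus, train
from metanner.preclassifier import fit_preclassifier
from metanner.rules import RuleAnnotator
from metanner.synthetic import (
    corpus_vocabulary,
    make_corpus,
    make_dictionary,
    make_wordvec_file,
    template_vocabulary,
)


@pytest.fixture(scope="session")
def names30() -> list[str]:
    _, names = make_dictionary(30, seed=7)
    return names


@pytest.fixture(scope="session")
def dict30(names30) -> MetaboliteDictionary:
    return MetaboliteDictionary(
        entries=set(names30), status={n: "detected" for n in names30}
    )


@pytest.fixture(scope="session")
def fixture_corpus(names30):
    """A mid-sized clean corpus (no typos) with plant-time gold spans."""
    return make_corpus(40, names30, typo_rate=0.0, seed=3)


@pytest.fixture(scope="session")
def big_fixture_sentences(names30):
    """>=1000 sentences for oracle-equivalence property tests."""
    fx = make_corpus(300, names30, typo_rate=0.0, seed=11)
    assert len(fx.sentences) >= 1000
    return fx.sentences[:1000]


@pytest.fixture(scope="session")
def rule_annotator(dict30) -> RuleAnnotator:
    return RuleAnnotator(dict30)


@pytest.fixture(scope="session")
def trained_model(names30, dict30, tmp_path_factory):
    """The scaled-down training setup: 200 sentences from a 30-name
    dictionary, context-free 300-d embeddings, 50 epochs, seed 7, reduced
    recurrent width.  Returns everything needed to annotate and evaluate."""
    fx = make_corpus(60, names30, typo_rate=0.0, seed=7)
    sents = fx.sentences[:200]
    keys = {(s.pmcid, s.sentence_id) for s in sents}
    gold = [g for g in fx.gold if (g.pmcid, g.sentence_id) in keys]
    train_s, val_s = sents[:-40], sents[-40:]
    pre = fit_preclassifier(
        dict30, template_vocabulary() + default_stopwords(), seed=7
    )
    vec_path = tmp_path_factory.mktemp("vec") / "vectors300.txt"
    make_wordvec_file(corpus_vocabulary(names30), 300, 7, vec_path)
    embedder = WordVectorEmbedder(vec_path)
    config = ModelConfig(
        embedding_kind="context_free_300", recurrent_units=32, epochs=50, seed=7
    )
    net = build_model(config)
    enc_train = encode_corpus(train_s, gold, pre, embedder, config)
    enc_val = encode_corpus(val_s, gold, pre, embedder, config)
    log = train(net, enc_train, enc_val, config)
    return {
        "net": net,
        "preclassifier": pre,
        "embedder": embedder,
        "config": config,
        "log": log,
        "train_sentences": train_s,
        "val_sentences": val_s,
        "gold": gold,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
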