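"""Model configuration, training behaviour and span prediction."""

import numpy as np
import pytest

from metanner.corpus_io import Sentence
from metanner.embeddings import HashedContextualEmbedder, WordVectorEmbedder
from metanner.ner import (
    ModelConfig,
    NERAnnotator,
    build_model,
    encode_corpus,
    train,
)
from metanner.synthetic import make_corpus


class TestConfig:
    def test_context_free_concat_width(self):
        cfg = ModelConfig(embedding_kind="context_free_300")
        assert cfg.concat_width == 556
        assert build_model(cfg).concat_width == 556

    def test_contextual_concat_width(self):
        cfg = ModelConfig(embedding_kind="contextual_768", recurrent_units=8,
                          conv_filters=256)
        assert cfg.concat_width == 1024
        assert build_model(cfg).concat_width == 1024

    def test_unknown_embedding_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(embedding_kind="context_free_100")

    def test_dropout_only_applies_to_contextual(self):
        assert ModelConfig(embedding_kind="context_free_300").effective_dropout == 0.0
        assert ModelConfig(embedding_kind="contextual_768").effective_dropout == 0.25

    def test_embedder_dimension_mismatch_rejected(self, trained_model):
        cfg = ModelConfig(embedding_kind="contextual_768", recurrent_units=8)
        with pytest.raises(ValueError):
            NERAnnotator(
                trained_model["net"],
                trained_model["preclassifier"],
                trained_model["embedder"],  # 300-d
                cfg,
            )


def _tiny_setup(names30, trained_model, epochs, seed=1):
    fx = make_corpus(6, names30, seed=41)
    sents = fx.sentences
    gold = fx.gold
    cfg = ModelConfig(
        embedding_kind="context_free_300",
        recurrent_units=8,
        conv_filters=16,
        epochs=epochs,
        seed=seed,
    )
    pre = trained_model["preclassifier"]
    emb = trained_model["embedder"]
    enc = encode_corpus(sents, gold, pre, emb, cfg)
    cut = max(len(enc) - 5, 1)
    return cfg, enc[:cut], enc[cut:]


class TestTrain:
    def test_one_epoch_run_returns_epoch_one(self, names30, trained_model):
        cfg, tr, va = _tiny_setup(names30, trained_model, epochs=1)
        net = build_model(cfg)
        log = train(net, tr, va, cfg)
        assert len(log.entries) == 1
        assert log.best_epoch == 1

    def test_same_seed_gives_identical_training_log(self, names30, trained_model):
        cfg, tr, va = _tiny_setup(names30, trained_model, epochs=3)
        log1 = train(build_model(cfg), tr, va, cfg)
        log2 = train(build_model(cfg), tr, va, cfg)
        assert log1.entries == log2.entries

    def test_best_epoch_attains_logged_maximum(self, trained_model):
        log = trained_model["log"]
        assert log.best_val_f1 == max(e["val_f1"] for e in log.entries)
        assert log.entries[log.best_epoch - 1]["val_f1"] == log.best_val_f1

    def test_empty_corpora_rejected(self, names30, trained_model):
        cfg, tr, va = _tiny_setup(names30, trained_model, epochs=1)
        net = build_model(cfg)
        with pytest.raises(ValueError):
            train(net, [], va, cfg)
        with pytest.raises(ValueError):
            train(net, tr, [], cfg)

    def test_log_csv_round_trip(self, trained_model, tmp_path):
        path = tmp_path / "log.csv"
        trained_model["log"].to_csv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "epoch,loss,val_f1"
        assert len(rows) == 1 + len(trained_model["log"].entries)


class TestPredict:
    def _annotator(self, trained_model):
        return NERAnnotator(
            trained_model["net"],
            trained_model["preclassifier"],
            trained_model["embedder"],
            trained_model["config"],
        )

    def test_planted_name_found_with_exact_span(self, trained_model, names30):
        ann = self._annotator(trained_model)
        name = next(n for n in names30 if " " not in n)
        text = f"Levels of {name} were higher in cases compared with controls."
        start = text.index(name)
        sent = Sentence("PMC1", "R00000", text)
        recs = ann.annotate_sentence(sent)
        assert any(r.start == start and r.end == start + len(name) for r in recs)

    def test_prediction_rows_deterministic(self, trained_model, names30):
        ann = self._annotator(trained_model)
        text = f"Levels of {names30[0]} were higher in cases compared with controls."
        assert ann.predict_spans(text) == ann.predict_spans(text)

    def test_empty_sentence_is_empty(self, trained_model):
        ann = self._annotator(trained_model)
        assert ann.predict_spans("") == []

    def test_windowed_processing_matches_whole_sentence(self, trained_model, names30):
        import dataclasses

        ann = self._annotator(trained_model)
        name = next(n for n in names30 if " " not in n)
        text = ("Samples were analysed using standard protocols. " * 4) + (
            f"Levels of {name} were higher in cases."
        )
        whole = ann.predict_spans(text)
        small_cfg = dataclasses.replace(
            trained_model["config"], max_tokens=16, window_overlap=8
        )
        windowed_ann = NERAnnotator(
            trained_model["net"],
            trained_model["preclassifier"],
            trained_model["embedder"],
            small_cfg,
        )
        windowed = windowed_ann.predict_spans(text)
        start = text.index(name)
        target = (start, start + len(name))
        assert any((s.start, s.end) == target for s in whole)
        assert any((s.start, s.end) == target for s in windowed)


class TestContextualPath:
    def test_contextual_model_trains_and_predicts(self, names30, trained_model):
        fx = make_corpus(6, names30, seed=42)
        cfg = ModelConfig(
            embedding_kind="contextual_768",
            recurrent_units=8,
            conv_filters=16,
            epochs=2,
            seed=2,
            tokenizer_id="chem_word",  # keep spans token-aligned
        )
        emb = HashedContextualEmbedder(dim=768, seed=2)
        pre = trained_model["preclassifier"]
        enc = encode_corpus(fx.sentences, fx.gold, pre, emb, cfg)
        net = build_model(cfg)
        log = train(net, enc[:-4], enc[-4:], cfg)
        assert len(log.entries) == 2
        ann = NERAnnotator(net, pre, emb, cfg)
        assert isinstance(ann.predict_spans("Nothing to see here."), list)

    def test_contextual_embedder_is_context_sensitive(self):
        emb = HashedContextualEmbedder(dim=32, seed=0)
        a = emb.embed(["glucose", "rose"])
        b = emb.embed(["glucose", "fell"])
        assert not np.allclose(a[0], b[0])
        # but deterministic for the same context
        assert np.allclose(a, emb.embed(["glucose", "rose"]))


def test_wordvec_embedder_oov_is_zero(tmp_path):
    from metanner.synthetic import make_wordvec_file

    path = make_wordvec_file(["alpha", "beta"], 5, 3, tmp_path / "v.txt")
    emb = WordVectorEmbedder(path)
    out = emb.embed(["alpha", "never-seen"])
    assert out.shape == (2, 5)
    assert np.any(out[0] != 0) and np.all(out[1] == 0)
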