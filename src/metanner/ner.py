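"""Sequence-labelling NER models: configuration, training and prediction.

The model scores each token of a sentence with a probability row over the
five BIOES classes.  Inputs per token are (a) name-internal features from
the dictionary-trained preclassifier, passed through a width-3 convolution
with 256 filters, and (b) a word embedding — either context-free (300-d
word-vector lookup, chem-word tokens) or contextual (768-d, subword
tokens, with channel dropout 0.25 on the embedding during training).  The
concatenation (256+300=556 or 256+768=1024 wide) feeds a bidirectional
LSTM and a per-token dense softmax.

Training runs a fixed number of epochs (default 50) and keeps the weights
of the epoch with the highest span-level F1 on the validation set.
Prediction decodes BIOES labels to character spans and then applies the
same post-processing fixups as the rule-based pipeline (adjacent-word
extension, bracket balancing, merging).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import AnnotationRecord, Sentence
from .embeddings import Embedder
from .network import Adam, BiLSTMTagger, pad_batch
from .preclassifier import Preclassifier
from .rules import Span, postprocess_spans
from .tagging import CLASS_INDEX, CLASSES, Token, bioes_to_spans, spans_to_bioes, tokenize

logger = logging.getLogger(__name__)

EMBEDDING_KINDS = {"context_free_300": 300, "contextual_768": 768}


@dataclass
class ModelConfig:
    embedding_kind: str = "context_free_300"
    conv_width: int = 3
    conv_filters: int = 256
    embed_dropout: float = 0.25  # applied for contextual embeddings only
    recurrent_units: int = 300
    epochs: int = 50
    seed: int = 0
    decode_policy: str = "conservative"
    learning_rate: float = 1e-3
    batch_size: int = 32
    #: probability of zeroing a token's whole embedding vector during
    #: training; emulates out-of-vocabulary tokens so the tagger learns to
    #: fall back on name-internal features and context
    word_dropout: float = 0.1
    tokenizer_id: str = ""
    max_tokens: int = 512  # longer sentences are windowed with overlap
    window_overlap: int = 32

    def __post_init__(self) -> None:
        if self.embedding_kind not in EMBEDDING_KINDS:
            raise ValueError(f"unknown embedding_kind {self.embedding_kind!r}")
        if self.conv_width % 2 == 0:
            raise ValueError("conv_width must be odd")
        if not self.tokenizer_id:
            self.tokenizer_id = (
                "chem_word" if self.embedding_kind == "context_free_300" else "subword"
            )

    @property
    def embed_dim(self) -> int:
        return EMBEDDING_KINDS[self.embedding_kind]

    @property
    def concat_width(self) -> int:
        return self.conv_filters + self.embed_dim

    @property
    def effective_dropout(self) -> float:
        return self.embed_dropout if self.embedding_kind == "contextual_768" else 0.0


@dataclass
class EncodedSentence:
    """One sentence prepared for the network."""

    sentence: Sentence
    tokens: list[Token]
    features: np.ndarray  # (n_tokens, 5) name-internal probability rows
    embeddings: np.ndarray  # (n_tokens, embed_dim)
    labels: np.ndarray | None = None  # (n_tokens,) int class indices
    gold_spans: list[Span] = field(default_factory=list)


def build_model(config: ModelConfig) -> BiLSTMTagger:
    """Instantiate the network for a configuration."""
    net = BiLSTMTagger(
        feat_dim=len(CLASSES),
        embed_dim=config.embed_dim,
        conv_width=config.conv_width,
        conv_filters=config.conv_filters,
        hidden=config.recurrent_units,
        n_classes=len(CLASSES),
        embed_dropout=config.effective_dropout,
        seed=config.seed,
    )
    assert net.concat_width == config.concat_width
    return net


def encode_sentence(
    sentence: Sentence,
    preclassifier: Preclassifier,
    embedder: Embedder,
    config: ModelConfig,
    gold_spans: Sequence[Span] | None = None,
) -> EncodedSentence:
    """Tokenise, score name-internal features, embed, and (optionally) label."""
    tokens = tokenize(sentence.text, config.tokenizer_id)
    token_texts = [t.text for t in tokens]
    feats = preclassifier.score_tokens(token_texts)
    embs = embedder.embed(token_texts)
    labels = None
    spans = list(gold_spans) if gold_spans is not None else []
    if gold_spans is not None:
        bioes = spans_to_bioes(tokens, spans, on_misaligned="snap")
        labels = np.array([CLASS_INDEX[b] for b in bioes], dtype=np.int64)
    return EncodedSentence(sentence, tokens, feats, embs, labels, spans)


def encode_corpus(
    sentences: Sequence[Sentence],
    annotations: Sequence[AnnotationRecord],
    preclassifier: Preclassifier,
    embedder: Embedder,
    config: ModelConfig,
) -> list[EncodedSentence]:
    """Encode sentences with their gold annotation spans as labels."""
    by_sentence: dict[tuple[str, str], list[Span]] = {}
    for a in annotations:
        by_sentence.setdefault((a.pmcid, a.sentence_id), []).append(
            Span(a.start, a.end, source="gold")
        )
    return [
        encode_sentence(
            s, preclassifier, embedder, config,
            gold_spans=by_sentence.get((s.pmcid, s.sentence_id), []),
        )
        for s in sentences
    ]


def _span_f1(pred: Sequence[Span], gold: Sequence[Span]) -> tuple[int, int, int]:
    p = {(s.start, s.end) for s in pred}
    g = {(s.start, s.end) for s in gold}
    tp = len(p & g)
    return tp, len(p) - tp, len(g) - tp


def evaluate_encoded(
    net: BiLSTMTagger,
    corpus: Sequence[EncodedSentence],
    config: ModelConfig,
    batch_size: int = 64,
) -> float:
    """Span-level F1 of decoded predictions against gold spans."""
    tp = fp = fn = 0
    for i in range(0, len(corpus), batch_size):
        chunk = [c for c in corpus[i : i + batch_size] if c.tokens]
        if not chunk:
            continue
        fb, eb, mask = pad_batch(
            [c.features for c in chunk], [c.embeddings for c in chunk]
        )
        probs, _ = net.forward(fb, eb, mask)
        for j, c in enumerate(chunk):
            n = len(c.tokens)
            spans = bioes_to_spans(c.tokens, probs[j, :n], policy=config.decode_policy)
            a, b_, c_ = _span_f1(spans, c.gold_spans)
            tp, fp, fn = tp + a, fp + b_, fn + c_
    for c in corpus:
        if not c.tokens:
            fn += len(c.gold_spans)
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


@dataclass
class TrainingLog:
    entries: list[dict] = field(default_factory=list)  # epoch, loss, val_f1
    best_epoch: int = -1
    best_val_f1: float = -1.0

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "val_f1"])
            writer.writeheader()
            writer.writerows(self.entries)


def train(
    net: BiLSTMTagger,
    train_corpus: Sequence[EncodedSentence],
    val_corpus: Sequence[EncodedSentence],
    config: ModelConfig,
) -> TrainingLog:
    """Train the tagger; the network is left holding the weights of the
    epoch with the best validation span-level F1.

    Deterministic for a fixed config seed and corpus; every stochastic
    component (shuffling, dropout) draws from one seeded generator.
    """
    if not train_corpus:
        raise ValueError("empty training corpus")
    if not val_corpus:
        raise ValueError("empty validation corpus")
    usable = [c for c in train_corpus if c.tokens and c.labels is not None]
    rng = np.random.default_rng(config.seed)
    opt = Adam(lr=config.learning_rate)
    log = TrainingLog()
    best_weights = net.get_weights()
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(usable))
        total_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            batch = [usable[j] for j in order[i : i + config.batch_size]]
            fb, eb, mask, lb = pad_batch(
                [c.features for c in batch],
                [c.embeddings for c in batch],
                [c.labels for c in batch],
            )
            if config.word_dropout > 0:
                keep = rng.random(eb.shape[:2]) >= config.word_dropout
                eb = eb * keep[..., None]
            loss, grads = net.loss_and_grads(fb, eb, mask, lb, rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.step(net.params, grads)
            total_loss += loss
            n_batches += 1
        val_f1 = evaluate_encoded(net, val_corpus, config)
        log.entries.append(
            {"epoch": epoch, "loss": total_loss / max(n_batches, 1), "val_f1": val_f1}
        )
        if val_f1 > log.best_val_f1:
            log.best_val_f1 = val_f1
            log.best_epoch = epoch
            best_weights = net.get_weights()
        logger.debug("epoch %d loss %.4f val_f1 %.4f", epoch, total_loss, val_f1)
    net.set_weights(best_weights)
    return log


# ---------------------------------------------------------------------------
# prediction


class NERAnnotator:
    """A trained model bundled with its preclassifier and embedder.

    Satisfies the same per-sentence annotator contract as the rule-based
    pipeline, so documents can be annotated with either interchangeably.
    """

    def __init__(
        self,
        net: BiLSTMTagger,
        preclassifier: Preclassifier,
        embedder: Embedder,
        config: ModelConfig,
        stopwords: Sequence[str] | None = None,
    ) -> None:
        if embedder.dim != config.embed_dim:
            raise ValueError(
                f"embedder dim {embedder.dim} != config {config.embed_dim}"
            )
        self.net = net
        self.preclassifier = preclassifier
        self.embedder = embedder
        self.config = config
        self.stopwords = list(stopwords) if stopwords is not None else None

    def _score_tokens(self, tokens: list[Token]) -> np.ndarray:
        """Class probabilities per token, windowing overlong sentences."""
        texts = [t.text for t in tokens]
        cfg = self.config
        if len(tokens) <= cfg.max_tokens:
            feats = self.preclassifier.score_tokens(texts)
            embs = self.embedder.embed(texts)
            fb, eb, mask = pad_batch([feats], [embs])
            probs, _ = self.net.forward(fb, eb, mask)
            return probs[0, : len(tokens)]
        # overlapping windows; keep the prediction from the window where the
        # token is furthest from a window edge
        out = np.zeros((len(tokens), len(CLASSES)))
        best_margin = np.full(len(tokens), -1)
        step = cfg.max_tokens - cfg.window_overlap
        for w0 in range(0, len(tokens), step):
            w1 = min(w0 + cfg.max_tokens, len(tokens))
            window = texts[w0:w1]
            feats = self.preclassifier.score_tokens(window)
            embs = self.embedder.embed(window)
            fb, eb, mask = pad_batch([feats], [embs])
            probs, _ = self.net.forward(fb, eb, mask)
            for k in range(w0, w1):
                margin = min(k - w0, w1 - 1 - k)
                if margin > best_margin[k]:
                    best_margin[k] = margin
                    out[k] = probs[0, k - w0]
            if w1 == len(tokens):
                break
        return out

    def predict_raw_spans(self, text: str) -> list[Span]:
        """Decoded spans with no post-processing fixups (used when linking
        abbreviation definitions, where incomplete-entity repair must not
        fire)."""
        tokens = tokenize(text, self.config.tokenizer_id)
        if not tokens:
            return []
        probs = self._score_tokens(tokens)
        return bioes_to_spans(tokens, probs, policy=self.config.decode_policy)

    def predict_spans(self, text: str) -> list[Span]:
        tokens = tokenize(text, self.config.tokenizer_id)
        if not tokens:
            return []
        probs = self._score_tokens(tokens)
        raw = bioes_to_spans(tokens, probs, policy=self.config.decode_policy)
        if not raw:
            return []
        return postprocess_spans(raw, text, self.stopwords)

    def annotate_sentence(self, sentence: Sentence) -> list[AnnotationRecord]:
        return [
            AnnotationRecord(
                pmcid=sentence.pmcid,
                sentence_id=sentence.sentence_id,
                start=sp.start,
                end=sp.end,
                entity=sentence.text[sp.start : sp.end],
            )
            for sp in self.predict_spans(sentence.text)
        ]


def predict(
    net: BiLSTMTagger,
    sentence: Sentence,
    embedder: Embedder,
    preclassifier: Preclassifier,
    config: ModelConfig,
    stopwords: Sequence[str] | None = None,
) -> list[AnnotationRecord]:
    """Functional wrapper: annotate one sentence with a trained model."""
    return NERAnnotator(net, preclassifier, embedder, config, stopwords).annotate_sentence(
        sentence
    )


def config_metadata(config: ModelConfig) -> dict:
    return asdict(config)
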