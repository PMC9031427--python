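"""Name-internal feature generator.

A token-level classifier is trained purely from the metabolite dictionary
(positive examples: dictionary entries tokenised, labelled B/I/E/S by
position) and a negative lexicon of common words (labelled O).  At
annotation time it scores each sentence token with a probability row over
(O, B, I, E, S); these rows are the "name-internal features" fed to the
sequence model alongside word embeddings.  No sentence context is used —
the classifier sees token shape and character n-grams only, which is what
lets it degrade gracefully on misspelled or unseen names.

Features per token: hashed character n-grams (lengths 1-3, 64 signed
buckets via CRC32) plus shape features (length, digit/hyphen/bracket/colon
presence, case pattern, vowel fraction).  The classifier family is any
probabilistic multi-class learner; the default is a random forest.
"""

from __future__ import annotations

import pickle
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .dictionary import MetaboliteDictionary
from .tagging import CLASSES, tokenize

N_HASH_BUCKETS = 64
_SHAPE_FEATURES = 8


def featurize_tokens(tokens: Sequence[str]) -> np.ndarray:
    """Deterministic (CRC32-hashed) character n-gram + shape features."""
    X = np.zeros((len(tokens), N_HASH_BUCKETS + _SHAPE_FEATURES), dtype=np.float64)
    for row, tok in enumerate(tokens):
        low = tok.lower()
        padded = f"^{low}$"
        for n in (1, 2, 3):
            for i in range(len(padded) - n + 1):
                gram = padded[i : i + n]
                h = zlib.crc32(gram.encode("utf-8"))
                X[row, h % N_HASH_BUCKETS] += 1.0
        norm = np.linalg.norm(X[row, :N_HASH_BUCKETS])
        if norm > 0:
            X[row, :N_HASH_BUCKETS] /= norm
        s = N_HASH_BUCKETS
        X[row, s + 0] = min(len(tok), 20) / 20.0
        X[row, s + 1] = float(any(c.isdigit() for c in tok))
        X[row, s + 2] = float("-" in tok)
        X[row, s + 3] = float(any(c in "()[]{}" for c in tok))
        X[row, s + 4] = float(":" in tok)
        X[row, s + 5] = float(tok.isupper() and len(tok) > 1)
        X[row, s + 6] = float(tok[:1].isupper())
        vowels = sum(c in "aeiou" for c in low)
        X[row, s + 7] = vowels / max(len(tok), 1)
    return X


def build_preclassifier_data(
    dictionary: MetaboliteDictionary,
    negative_lexicon: Iterable[str],
    tokenizer_id: str = "chem_word",
) -> tuple[list[str], list[str]]:
    """Token strings and BIOES-by-position labels for training.

    Each dictionary entry is tokenised; a single-token entry yields one S
    token, multi-token entries yield B (I...) E.  Negative-lexicon tokens
    are labelled O.
    """
    if not dictionary.entries:
        raise ValueError("empty dictionary")
    tokens: list[str] = []
    labels: list[str] = []
    for entry in sorted(dictionary.entries):
        toks = [t.text for t in tokenize(entry, tokenizer_id)]
        if not toks:
            continue
        if len(toks) == 1:
            tokens.append(toks[0])
            labels.append("S")
        else:
            tokens.append(toks[0])
            labels.append("B")
            for t in toks[1:-1]:
                tokens.append(t)
                labels.append("I")
            tokens.append(toks[-1])
            labels.append("E")
    for word in sorted(set(negative_lexicon)):
        if word:
            tokens.append(word)
            labels.append("O")
    return tokens, labels


@dataclass
class Preclassifier:
    """A trained name-internal feature scorer with its provenance."""

    model: RandomForestClassifier
    seed: int
    dictionary_hash: str
    tokenizer_id: str = "chem_word"

    def score_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        return score_tokens(self, tokens)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {
                    "format_version": 1,
                    "seed": self.seed,
                    "dictionary_hash": self.dictionary_hash,
                    "tokenizer_id": self.tokenizer_id,
                    "model": self.model,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "Preclassifier":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        return cls(
            model=blob["model"],
            seed=blob["seed"],
            dictionary_hash=blob["dictionary_hash"],
            tokenizer_id=blob["tokenizer_id"],
        )


def _dictionary_hash(d: MetaboliteDictionary) -> str:
    joined = "\n".join(sorted(d.entries)).encode("utf-8")
    return format(zlib.crc32(joined), "08x")


def train_preclassifier(
    tokens: Sequence[str],
    labels: Sequence[str],
    seed: int = 0,
    n_estimators: int = 64,
    dictionary: MetaboliteDictionary | None = None,
    tokenizer_id: str = "chem_word",
) -> Preclassifier:
    """Train the name-internal token classifier (deterministic per seed)."""
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 label classes to train")
    X = featurize_tokens(tokens)
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    clf.fit(X, list(labels))
    return Preclassifier(
        model=clf,
        seed=seed,
        dictionary_hash=_dictionary_hash(dictionary) if dictionary else "",
        tokenizer_id=tokenizer_id,
    )


def score_tokens(pre: Preclassifier, tokens: Sequence[str]) -> np.ndarray:
    """Per-token probability rows over the fixed class order (O,B,I,E,S).

    Classes absent from training get probability 0; rows sum to 1.
    """
    out = np.zeros((len(tokens), len(CLASSES)), dtype=np.float64)
    if not tokens:
        return out
    probs = pre.model.predict_proba(featurize_tokens(tokens))
    for col, cls in enumerate(pre.model.classes_):
        out[:, CLASSES.index(cls)] = probs[:, col]
    return out


def fit_preclassifier(
    dictionary: MetaboliteDictionary,
    negative_lexicon: Iterable[str],
    seed: int = 0,
    tokenizer_id: str = "chem_word",
) -> Preclassifier:
    """Convenience: build data and train in one call."""
    tokens, labels = build_preclassifier_data(dictionary, negative_lexicon, tokenizer_id)
    return train_preclassifier(
        tokens, labels, seed=seed, dictionary=dictionary, tokenizer_id=tokenizer_id
    )
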