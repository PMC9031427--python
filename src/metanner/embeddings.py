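"""Embedder contract and implementations.

An embedder maps a token-string sequence to per-token vectors of a fixed
dimension.  Two kinds are supported:

* context-free (300-d by default): one fixed vector per surface form,
  loaded from a plain-text word-vector file (``token v1 ... v300`` per
  line); out-of-vocabulary tokens embed to the zero vector;
* contextual (768-d by default): per-token vectors that depend on the
  surrounding tokens, normally a transformer's last hidden layer.  Since
  pretrained weights are consumed through this contract rather than
  shipped, a deterministic *synthetic* contextual embedder is provided for
  testing: hash-seeded token vectors mixed with their neighbours.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np


class Embedder(Protocol):
    dim: int

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        """(len(tokens), dim) array; deterministic in inference mode."""
        ...


class WordVectorEmbedder:
    """Context-free embeddings from a text word-vector file."""

    def __init__(self, path: str | Path, dim: int | None = None):
        self.vectors: dict[str, np.ndarray] = {}
        self.dim = dim or 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < 2:
                    continue
                vec = np.array([float(x) for x in parts[1:]], dtype=np.float64)
                if self.dim == 0:
                    self.dim = vec.shape[0]
                elif vec.shape[0] != self.dim:
                    raise ValueError(
                        f"inconsistent vector width {vec.shape[0]} != {self.dim}"
                    )
                self.vectors[parts[0]] = vec
        if self.dim == 0:
            raise ValueError(f"no vectors found in {path}")

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(tokens), self.dim), dtype=np.float64)
        for i, tok in enumerate(tokens):
            vec = self.vectors.get(tok)
            if vec is None:
                vec = self.vectors.get(tok.lower())
            if vec is not None:
                out[i] = vec
        return out


class HashedContextualEmbedder:
    """Synthetic stand-in for a transformer last-hidden-layer embedder.

    Each token's base vector is drawn from an RNG seeded by a CRC32 of the
    token (plus a global seed); the output mixes each base vector with its
    neighbours so representations are context-dependent, then L2-normalises.
    Deterministic, vocabulary-free, and *not* a trained language model —
    suitable only for exercising the contextual-embedding code path.
    """

    def __init__(self, dim: int = 768, seed: int = 0, mix: float = 0.15):
        self.dim = dim
        self.seed = seed
        self.mix = mix
        self._cache: dict[str, np.ndarray] = {}

    def _base(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            h = zlib.crc32(token.encode("utf-8")) ^ (self.seed & 0xFFFFFFFF)
            rng = np.random.default_rng(h)
            vec = rng.standard_normal(self.dim)
            self._cache[token] = vec
        return vec

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        n = len(tokens)
        if n == 0:
            return np.zeros((0, self.dim), dtype=np.float64)
        base = np.stack([self._base(t) for t in tokens])
        out = (1.0 - 2 * self.mix) * base
        out[1:] += self.mix * base[:-1]
        out[:-1] += self.mix * base[1:]
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return out / norms
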