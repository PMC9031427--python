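"""Tokenisation contracts and BIOES span<->label conversion.

Two tokenizer families are registered: ``chem_word`` (a rule-based word
tokenizer that keeps hyphens, digits, colons and brackets inside
chemistry-like tokens, in the spirit of chemistry text-mining tokenizers)
and ``subword`` (delegates to a pluggable backend mapping text to character
spans; a deterministic fixed-width splitter is the default backend so the
contract is exercisable without pretrained vocabularies).

Labels use the BIOES scheme over class order ``("O", "B", "I", "E", "S")``:
B/I/E mark the beginning/inside/end of multi-token entities, S single-token
entities, O everything else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .rules import Span

#: fixed class order for label indices and probability columns
CLASSES: tuple[str, ...] = ("O", "B", "I", "E", "S")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

_PUNCT = set("()[]{}.,;:!?'\"")
_STRIP_TRAIL = set(".,;!?")


class AlignmentError(ValueError):
    """A span boundary does not coincide with token boundaries."""


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.text):
            raise ValueError("token text/offset length mismatch")


# ---------------------------------------------------------------------------
# tokenizers


def _chem_word_chunk(chunk: str, offset: int) -> list[Token]:
    """Tokenise one whitespace-delimited chunk.

    Chunks containing a digit are chemistry-like: only trailing sentence
    punctuation and unmatched trailing brackets are peeled off.  Other
    chunks shed all leading/trailing punctuation as separate tokens.
    """
    tokens: list[Token] = []
    start, end = 0, len(chunk)
    lead: list[tuple[str, int]] = []
    trail: list[tuple[str, int]] = []
    chemistry = any(ch.isdigit() for ch in chunk)
    if chemistry:
        while end > start and (
            chunk[end - 1] in _STRIP_TRAIL
            or (
                chunk[end - 1] in ")]}"
                and chunk.count({"(": "(", ")": "(", "]": "[", "}": "{"}[chunk[end - 1]], start, end)
                < chunk.count(chunk[end - 1], start, end)
            )
        ):
            trail.append((chunk[end - 1], end - 1))
            end -= 1
    else:
        while end > start and chunk[end - 1] in _PUNCT:
            trail.append((chunk[end - 1], end - 1))
            end -= 1
        while start < end and chunk[start] in _PUNCT:
            lead.append((chunk[start], start))
            start += 1
    for ch, pos in lead:
        tokens.append(Token(ch, offset + pos, offset + pos + 1))
    if end > start:
        tokens.append(Token(chunk[start:end], offset + start, offset + end))
    for ch, pos in reversed(trail):
        tokens.append(Token(ch, offset + pos, offset + pos + 1))
    return tokens


def chem_word_tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        tokens.extend(_chem_word_chunk(m.group(0), m.start()))
    return tokens


def fixed_width_subword_spans(text: str, width: int = 4) -> list[tuple[int, int]]:
    """Default subword backend: split each non-space run into pieces of at
    most ``width`` characters.  Deterministic and vocabulary-free."""
    spans: list[tuple[int, int]] = []
    for m in re.finditer(r"\S+", text):
        s, e = m.start(), m.end()
        for i in range(s, e, width):
            spans.append((i, min(i + width, e)))
    return spans


#: registry of tokenizer backends keyed by id
SubwordBackend = Callable[[str], list[tuple[int, int]]]
_REGISTRY: dict[str, Callable[[str], list[Token]]] = {}


def register_tokenizer(tokenizer_id: str, fn: Callable[[str], list[Token]]) -> None:
    _REGISTRY[tokenizer_id] = fn


def _subword_tokenize(text: str) -> list[Token]:
    return [Token(text[s:e], s, e) for s, e in fixed_width_subword_spans(text)]


register_tokenizer("chem_word", chem_word_tokenize)
register_tokenizer("subword", _subword_tokenize)


def tokenize(text: str, tokenizer_id: str = "chem_word") -> list[Token]:
    """Tokenise ``text`` with a registered backend; offsets index ``text``."""
    if tokenizer_id not in _REGISTRY:
        raise KeyError(
            f"unknown tokenizer {tokenizer_id!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[tokenizer_id](text)


# ---------------------------------------------------------------------------
# BIOES encoding / decoding


def spans_to_bioes(
    tokens: Sequence[Token],
    spans: Sequence[Span],
    on_misaligned: str = "error",
) -> list[str]:
    """Label tokens with BIOES for a set of disjoint entity spans.

    Span boundaries must coincide with token boundaries; with
    ``on_misaligned="snap"`` a span is grown to the smallest covering run of
    tokens instead of raising.
    """
    labels = ["O"] * len(tokens)
    starts = {t.start: i for i, t in enumerate(tokens)}
    ends = {t.end: i for i, t in enumerate(tokens)}
    for sp in sorted(spans):
        if sp.start in starts and sp.end in ends:
            i, j = starts[sp.start], ends[sp.end]
        elif on_misaligned == "snap":
            covering = [
                k for k, t in enumerate(tokens) if t.end > sp.start and t.start < sp.end
            ]
            if not covering:
                continue
            i, j = covering[0], covering[-1]
        else:
            raise AlignmentError(
                f"span [{sp.start}, {sp.end}) not aligned to token boundaries"
            )
        if i == j:
            labels[i] = "S"
        else:
            labels[i] = "B"
            for k in range(i + 1, j):
                labels[k] = "I"
            labels[j] = "E"
    return labels


def _labels_from(labels_or_probs) -> list[str]:
    arr = np.asarray(labels_or_probs)
    if arr.dtype.kind in "fiu" and arr.ndim == 2:
        return [CLASSES[i] for i in arr.argmax(axis=1)]
    return [str(x) for x in np.atleast_1d(labels_or_probs)]


def bioes_to_spans(
    tokens: Sequence[Token],
    labels_or_probs,
    policy: str = "conservative",
) -> list[Span]:
    """Decode BIOES labels (or per-token class-probability rows, argmaxed)
    into character spans.

    Repair of illegal sequences is explicit: ``conservative`` drops orphan
    I/E labels and unclosed B-blocks; ``permissive`` turns every maximal run
    of non-O labels into one span.
    """
    labels = _labels_from(labels_or_probs)
    if len(labels) != len(tokens):
        raise ValueError(f"{len(labels)} labels for {len(tokens)} tokens")
    if policy not in {"conservative", "permissive"}:
        raise ValueError(f"unknown repair policy {policy!r}")

    spans: list[Span] = []
    if policy == "permissive":
        i = 0
        while i < len(labels):
            if labels[i] == "O":
                i += 1
                continue
            j = i
            while j + 1 < len(labels) and labels[j + 1] != "O":
                j += 1
            spans.append(Span(tokens[i].start, tokens[j].end, source="model"))
            i = j + 1
        return spans

    i = 0
    while i < len(labels):
        lab = labels[i]
        if lab == "S":
            spans.append(Span(tokens[i].start, tokens[i].end, source="model"))
            i += 1
        elif lab == "B":
            j = i + 1
            while j < len(labels) and labels[j] == "I":
                j += 1
            if j < len(labels) and labels[j] == "E":
                spans.append(Span(tokens[i].start, tokens[j].end, source="model"))
                i = j + 1
            else:  # unclosed block: drop
                i = j
        else:  # O, or orphan I/E: drop
            i += 1
    return spans
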