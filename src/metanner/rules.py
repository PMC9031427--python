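"""Rule-based metabolite annotation.

The pipeline combines dictionary matching and regular-expression partial
matching, then post-processes candidate spans with three fixups run to a
fixpoint:

* adjacent-word extension — prepend/append neighbouring words under a small
  set of rules (hyphen/digit endings, comma+digit starts, and the follower
  words "acid", "isomer", "ester", "ether"), never across stopwords;
* bracket balancing — an entity missing one side of a ()/[]/{} pair is
  enclosed by the missing bracket, by growing the span when the missing
  bracket is the adjacent sentence character;
* merging — entities that overlap or are separated only by whitespace are
  merged into one.

Spans are 0-based, end-exclusive character offsets into the sentence; every
emitted record's entity text equals its sentence substring.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import AnnotationRecord, Sentence
from .dictionary import MetaboliteDictionary, default_stopwords

logger = logging.getLogger(__name__)

#: characters treated as word-internal for boundary checks: letters, digits
#: and hyphens (so "glucose" does not match inside "glucoses" or "D-glucose")
_WORD_CHARS = re.compile(r"[A-Za-z0-9-]")

_BRACKET_PAIRS = (("(", ")"), ("[", "]"), ("{", "}"))

#: follower words that may be appended to an entity
APPEND_WORDS = frozenset({"acid", "isomer", "ester", "ether"})


class FixpointError(RuntimeError):
    """Post-processing failed to reach a fixpoint within the iteration cap."""


@dataclass(frozen=True, order=True)
class Span:
    start: int
    end: int
    source: str = field(default="dictionary", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")


@dataclass
class PatternSet:
    """An ordered, named set of regular-expression strings."""

    patterns: list[str]
    name: str = "custom"
    version: str = "0"

    def __post_init__(self) -> None:
        self._compiled = [re.compile(p) for p in self.patterns]

    @property
    def compiled(self) -> list[re.Pattern]:
        return self._compiled

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "PatternSet":
        path = Path(path)
        lines = [
            ln.strip()
            for ln in path.read_text("utf-8").splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls(patterns=lines, name=name or path.stem)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# pattern set {self.name} v{self.version}\n")
            for p in self.patterns:
                fh.write(p + "\n")


def default_patterns() -> PatternSet:
    """The shipped metabolite-morphology pattern set (user-replaceable)."""
    text = resources.files("metanner").joinpath("data", "patterns.txt").read_text("utf-8")
    lines = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    return PatternSet(patterns=lines, name="default", version="1")


# ---------------------------------------------------------------------------
# matching


def _is_word_char(ch: str) -> bool:
    return bool(_WORD_CHARS.match(ch))


def _at_word_boundary(text: str, start: int, end: int) -> bool:
    before_ok = start == 0 or not _is_word_char(text[start - 1])
    after_ok = end == len(text) or not _is_word_char(text[end])
    return before_ok and after_ok


def dictionary_match(text: str, d: MetaboliteDictionary) -> list[Span]:
    """All case-insensitive, word-bounded occurrences of dictionary entries,
    overlaps resolved longest-match-first."""
    lowered = text.lower()
    candidates: list[Span] = []
    for entry in d.entries:
        needle = entry.lower()
        pos = lowered.find(needle)
        while pos != -1:
            end = pos + len(needle)
            if _at_word_boundary(text, pos, end):
                candidates.append(Span(pos, end, source="dictionary"))
            pos = lowered.find(needle, pos + 1)
    return resolve_longest(candidates)


def resolve_longest(spans: Iterable[Span]) -> list[Span]:
    """Keep maximal spans: longest first, discarding any span overlapping an
    already-kept one; ties broken by earlier start."""
    kept: list[Span] = []
    for sp in sorted(set(spans), key=lambda s: (-(s.end - s.start), s.start)):
        if all(sp.end <= k.start or sp.start >= k.end for k in kept):
            kept.append(sp)
    return sorted(kept)


def _word_extent(text: str, start: int, end: int) -> tuple[int, int]:
    """Expand [start, end) to the whitespace-delimited word(s) it touches,
    then shed trailing sentence punctuation."""
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    while end < len(text) and not text[end].isspace():
        end += 1
    while end > start and text[end - 1] in ".,;!?":
        end -= 1
    while start < end and text[start] in ".,;!?":
        start += 1
    return start, end


def regex_match_and_expand(
    text: str,
    patterns: PatternSet,
    per_pattern_timeout: float = 1.0,
) -> list[Span]:
    """Partial regex matches expanded to the full word(s) they touch.

    Each pattern runs under a best-effort wall-clock budget (checked between
    matches); a pattern that exceeds it is skipped with a warning.
    """
    spans: set[Span] = set()
    for pat in patterns.compiled:
        t0 = time.monotonic()
        timed_out = False
        for m in pat.finditer(text):
            if time.monotonic() - t0 > per_pattern_timeout:
                timed_out = True
                break
            if m.start() == m.end():
                continue
            s, e = _word_extent(text, m.start(), m.end())
            if s < e:
                spans.add(Span(s, e, source="regex"))
        if timed_out:
            logger.warning("pattern %r exceeded %.1fs; skipped", pat.pattern, per_pattern_timeout)
    return sorted(spans)


# ---------------------------------------------------------------------------
# fixups


def _prev_word(text: str, start: int) -> tuple[int, int] | None:
    """The whitespace-separated word immediately before position ``start``."""
    i = start
    while i > 0 and text[i - 1].isspace():
        i -= 1
    if i == start or i == 0:  # no separating whitespace, or sentence start
        return None
    end = i
    while i > 0 and not text[i - 1].isspace():
        i -= 1
    return (i, end)


def _next_word(text: str, end: int) -> tuple[int, int] | None:
    i = end
    while i < len(text) and text[i].isspace():
        i += 1
    if i == end or i == len(text):
        return None
    start = i
    while i < len(text) and not text[i].isspace():
        i += 1
    return (start, i)


_COMMA_DIGIT = re.compile(r"^,\d")


def extend_adjacent(
    span: Span,
    text: str,
    stopwords: Iterable[str] | None = None,
) -> Span:
    """Grow a span over adjacent words while the extension rules fire.

    Prepend the preceding word when it ends with a hyphen or a digit, when
    the entity starts with ","+digit, or when the entity's first word starts
    with a hyphen — never when the preceding word is a stopword.  Append the
    following word under the mirrored rules, plus when it is one of "acid",
    "isomer", "ester" or "ether".  Applied repeatedly until no rule fires.
    """
    stop = {s.casefold() for s in (stopwords if stopwords is not None else default_stopwords())}
    start, end = span.start, span.end
    changed = True
    while changed:
        changed = False
        entity = text[start:end]
        prev = _prev_word(text, start)
        if prev is not None:
            pw = text[prev[0] : prev[1]]
            pw_core = pw.strip(".,;!?")
            if pw_core.casefold() not in stop and pw_core:
                fires = (
                    pw.endswith("-")
                    or (pw and pw[-1].isdigit())
                    or bool(_COMMA_DIGIT.match(entity))
                    or entity.split()[0].startswith("-")
                )
                if fires:
                    start = prev[0]
                    changed = True
                    continue
        nxt = _next_word(text, end)
        if nxt is not None:
            nw = text[nxt[0] : nxt[1]]
            nw_core = nw.strip(".,;!?")
            if nw_core.casefold() not in stop and nw_core:
                fires = (
                    entity.endswith("-")
                    or (entity and entity[-1].isdigit())
                    or bool(_COMMA_DIGIT.match(nw))
                    or nw.startswith("-")
                    or nw_core.casefold() in APPEND_WORDS
                )
                if fires:
                    new_end = nxt[1]
                    # never end an entity on trailing sentence punctuation
                    while new_end > end and text[new_end - 1] in ".,;!?":
                        new_end -= 1
                    if new_end > end:
                        end = new_end
                        changed = True
    return Span(start, end, source="extended" if (start, end) != (span.start, span.end) else span.source)


def balance_brackets(entity_text: str) -> str:
    """Enclose an entity with the missing side of any unbalanced bracket
    pair; balanced input is returned unchanged."""
    out = entity_text
    for open_b, close_b in _BRACKET_PAIRS:
        n_open = out.count(open_b)
        n_close = out.count(close_b)
        if n_open > n_close:
            out = out + close_b * (n_open - n_close)
        elif n_close > n_open:
            out = open_b * (n_close - n_open) + out
    return out


def _balance_span(span: Span, text: str) -> Span:
    """Grow a span so its text balances brackets, but only when the missing
    bracket is the adjacent character in the sentence (spans must remain
    substrings; otherwise the fix is left as a virtual, unapplied repair)."""
    start, end = span.start, span.end
    changed = True
    while changed:
        changed = False
        ent = text[start:end]
        for open_b, close_b in _BRACKET_PAIRS:
            n_open = ent.count(open_b)
            n_close = ent.count(close_b)
            if n_open > n_close and end < len(text) and text[end] == close_b:
                end += 1
                changed = True
                break
            if n_close > n_open and start > 0 and text[start - 1] == open_b:
                start -= 1
                changed = True
                break
    if (start, end) == (span.start, span.end):
        return span
    return Span(start, end, source="extended")


def merge_spans(spans: Sequence[Span], text: str) -> list[Span]:
    """Transitive closure of the merge relation: spans that overlap, touch,
    or are separated only by whitespace become one span."""
    if not spans:
        return []
    ordered = sorted(set(spans))
    merged: list[Span] = [ordered[0]]
    for sp in ordered[1:]:
        last = merged[-1]
        gap = text[last.end : sp.start]
        if sp.start <= last.end or (gap and gap.isspace()) or not gap:
            if sp.end > last.end:
                src = "merged" if sp.start > last.end or sp.source != last.source else last.source
                merged[-1] = Span(last.start, sp.end, source=src)
        else:
            merged.append(sp)
    return merged


# ---------------------------------------------------------------------------
# the full per-sentence pipeline


def postprocess_spans(
    spans: Sequence[Span],
    text: str,
    stopwords: Iterable[str] | None = None,
    max_iterations: int = 20,
) -> list[Span]:
    """Run {extend, balance, merge} recursively until the span set is stable.

    Shared by the rule annotator and the sequence models (which apply the
    same fixups to decoded spans).
    """
    stop = list(stopwords) if stopwords is not None else default_stopwords()
    current = sorted(set(spans))
    for _ in range(max_iterations):
        extended = [extend_adjacent(sp, text, stop) for sp in current]
        balanced = [_balance_span(sp, text) for sp in extended]
        merged = merge_spans(balanced, text)
        if merged == current:
            return merged
        current = merged
    raise FixpointError(
        f"post-processing did not converge in {max_iterations} "
        f"iterations for sentence: {text[:80]!r}"
    )


class RuleAnnotator:
    """Dictionary + regex annotator with recursive post-processing."""

    def __init__(
        self,
        dictionary: MetaboliteDictionary,
        patterns: PatternSet | None = None,
        stopwords: Iterable[str] | None = None,
        max_iterations: int = 20,
    ) -> None:
        self.dictionary = dictionary
        self.patterns = patterns if patterns is not None else default_patterns()
        self.stopwords = list(stopwords) if stopwords is not None else default_stopwords()
        self.max_iterations = max_iterations

    def match_spans(self, text: str) -> list[Span]:
        """Raw dictionary + regex candidate spans, no fixups."""
        return sorted(
            set(dictionary_match(text, self.dictionary))
            | set(regex_match_and_expand(text, self.patterns))
        )

    def postprocess(self, spans: Sequence[Span], text: str) -> list[Span]:
        """Run {extend, balance, merge} recursively to a fixpoint."""
        return postprocess_spans(spans, text, self.stopwords, self.max_iterations)

    def annotate_text(self, text: str) -> list[Span]:
        return self.postprocess(self.match_spans(text), text)

    def annotate_sentence(self, sentence: Sentence) -> list[AnnotationRecord]:
        """Annotate one identified sentence; each record's entity equals its
        sentence substring."""
        return [
            AnnotationRecord(
                pmcid=sentence.pmcid,
                sentence_id=sentence.sentence_id,
                start=sp.start,
                end=sp.end,
                entity=sentence.text[sp.start : sp.end],
            )
            for sp in self.annotate_text(sentence.text)
        ]


def annotate_sentence(
    sentence: Sentence,
    dictionary: MetaboliteDictionary,
    patterns: PatternSet | None = None,
    stopwords: Iterable[str] | None = None,
) -> list[AnnotationRecord]:
    """Functional wrapper around :class:`RuleAnnotator` for one sentence."""
    return RuleAnnotator(dictionary, patterns, stopwords).annotate_sentence(sentence)
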