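"""Reading article JSON, sentence identification, and corpus file I/O.

Articles arrive as up to three JSON files per publication (maintext, table,
abbreviation) in the BioC-style dialect produced by upstream HTML
standardisation.  Maintext paragraphs carry an IAO (Information Artifact
Ontology) term naming the section type; only the textual abstract (A),
methods (M), results (R) and discussion (D) sections are kept — combined
results-and-discussion sections are kept with group code ``RD`` but share
the ``R`` letter in sentence identifiers.  Introductions are dropped.

Sentences are identified by a six-character ID: one section letter plus two
digits for the 0-based subsection index and three digits for the 0-based
sentence index within the subsection (e.g. ``M01001`` is the second sentence
of the second methods subsection).

Character offsets are 0-based and end-exclusive everywhere.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

#: section letters usable in sentence identifiers
ID_LETTERS = ("A", "M", "R", "D")

SENTENCE_ID_RE = re.compile(r"^[AMRD]\d{5}$")


class SchemaError(ValueError):
    """A JSON input is missing required keys."""


class CorpusIntegrityError(ValueError):
    """An annotation references a sentence that does not exist."""


class CapacityError(ValueError):
    """The sentence-ID scheme cannot encode the requested index."""


@dataclass
class Section:
    """A filtered article section.

    ``code`` is the section group (``A``/``M``/``R``/``D`` or combined
    ``RD``); ``id_letter`` is the letter used in sentence IDs (``R`` for
    ``RD``).  ``subsections`` is an ordered list of text blocks.
    """

    code: str
    iao_term: str
    subsections: list[str] = field(default_factory=list)

    @property
    def id_letter(self) -> str:
        return "R" if self.code == "RD" else self.code


@dataclass
class Article:
    pmcid: str
    sections: list[Section] = field(default_factory=list)
    tables: list[list[list[str]]] = field(default_factory=list)
    abbreviations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pmcid:
            raise ValueError("Article.pmcid must be non-empty")


@dataclass(frozen=True)
class Sentence:
    """A sentence with its article and positional identifiers.

    ``section_group`` keeps the evaluation grouping (A/M/R/RD/D) which can
    differ from the ID letter for combined results-and-discussion sections.
    """

    pmcid: str
    sentence_id: str
    text: str
    section_group: str = ""

    def __post_init__(self) -> None:
        if not SENTENCE_ID_RE.match(self.sentence_id):
            raise ValueError(f"bad sentence_id {self.sentence_id!r}")
        if not self.text:
            raise ValueError("empty sentence text")
        if not self.section_group:
            object.__setattr__(self, "section_group", self.sentence_id[0])


@dataclass(frozen=True)
class AnnotationRecord:
    """A five-field span record: article, sentence, [start, end), entity."""

    pmcid: str
    sentence_id: str
    start: int
    end: int
    entity: str
    source: str = "text"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.pmcid, self.sentence_id, self.start, self.end)


# ---------------------------------------------------------------------------
# IAO term -> section code

_IAO_PATTERNS: list[tuple[str, str]] = [
    ("results and discussion", "RD"),
    ("discussion", "D"),
    ("results", "R"),
    ("materials", "M"),
    ("methods", "M"),
    ("textual abstract", "A"),
    ("abstract", "A"),
]


def section_code_for_iao(iao_term: str) -> str | None:
    """Map an IAO section term to A/M/R/D/RD, or None if out of scope."""
    t = iao_term.strip().lower()
    if "introduction" in t:
        return None
    for pat, code in _IAO_PATTERNS:
        if pat in t:
            return code
    return None


# ---------------------------------------------------------------------------
# reading article JSON


def _load_json(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {path}: {exc}") from exc


def read_article(
    maintext_path: str | Path,
    table_path: str | Path | None = None,
    abbrev_path: str | Path | None = None,
) -> Article:
    """Read one article from its maintext (and optional table/abbreviation)
    JSON files, keeping only A/M/R/D(+RD) sections.

    The maintext file needs keys ``pmcid`` and ``paragraphs``; each paragraph
    needs ``body`` and ``IAO_term`` (``section_heading`` and
    ``subsection_heading`` are tolerated but unused).  Consecutive paragraphs
    with the same section code are grouped into one Section, each paragraph
    body becoming one subsection block.
    """
    doc = _load_json(maintext_path)
    missing = [k for k in ("pmcid", "paragraphs") if k not in doc]
    if missing:
        raise SchemaError(f"{maintext_path}: missing keys {missing}")

    by_code: dict[str, Section] = {}
    order: list[str] = []
    for i, para in enumerate(doc["paragraphs"]):
        miss = [k for k in ("body", "IAO_term") if k not in para]
        if miss:
            raise SchemaError(f"{maintext_path}: paragraph {i} missing keys {miss}")
        code = section_code_for_iao(para["IAO_term"])
        if code is None:
            continue
        body = str(para["body"]).strip()
        if not body:
            continue
        if code not in by_code:
            by_code[code] = Section(code=code, iao_term=para["IAO_term"])
            order.append(code)
        by_code[code].subsections.append(body)

    if not by_code:
        logger.warning("%s: no abstract/methods/results/discussion sections", maintext_path)

    tables: list[list[list[str]]] = []
    if table_path is not None:
        tdoc = _load_json(table_path)
        if "tables" not in tdoc:
            raise SchemaError(f"{table_path}: missing keys ['tables']")
        for tab in tdoc["tables"]:
            rows = tab["rows"] if isinstance(tab, dict) else tab
            tables.append([[str(c) for c in row] for row in rows])

    abbreviations: dict[str, str] = {}
    if abbrev_path is not None:
        adoc = _load_json(abbrev_path)
        mapping = adoc.get("abbreviations", adoc) if isinstance(adoc, dict) else None
        if not isinstance(mapping, dict):
            raise SchemaError(f"{abbrev_path}: expected an abbreviation mapping")
        abbreviations = {str(k): str(v) for k, v in mapping.items()}

    return Article(
        pmcid=str(doc["pmcid"]),
        sections=[by_code[c] for c in order],
        tables=tables,
        abbreviations=abbreviations,
    )


# ---------------------------------------------------------------------------
# sentence splitting

#: contract: text -> list of (start, end) character spans, in order
SentenceSplitter = Callable[[str], list[tuple[int, int]]]

# do not break after common abbreviations or initials
_NO_BREAK_BEFORE_DOT = re.compile(r"(?:\b(?:e\.g|i\.e|et al|Fig|fig|cf|vs|ca|approx|no|No)|\b[A-Z])$")
_BOUNDARY = re.compile(r"[.!?]+(\s+)(?=[A-Z0-9(\[\"'])")


def default_sentence_splitter(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence splitter.

    Splits at ``.``/``!``/``?`` followed by whitespace and an upper-case or
    numeric continuation, but not after decimal points (no whitespace),
    "e.g."/"i.e.", figure references or single-letter initials.  Any
    splitter honouring the (start, end) span contract may replace it.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        before = text[: m.start()]
        if _NO_BREAK_BEFORE_DOT.search(before):
            continue
        end = m.start() + len(m.group(0)) - len(m.group(1))
        if end > start:
            spans.append((start, end))
        start = m.end()
    if start < len(text):
        chunk = text[start:].rstrip()
        if chunk:
            spans.append((start, start + len(chunk)))
    # trim leading whitespace of each span
    out = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        if s < e:
            out.append((s, e))
    return out


def split_and_identify(
    article: Article,
    splitter: SentenceSplitter | None = None,
) -> list[Sentence]:
    """Split an article's subsections into identified sentences.

    The sentence ID is the section letter + 2-digit subsection index +
    3-digit sentence index, all 0-based; raises :class:`CapacityError` when
    an article exceeds 100 subsections per letter or 1000 sentences per
    subsection.
    """
    splitter = splitter or default_sentence_splitter
    sentences: list[Sentence] = []
    sub_counter: dict[str, int] = {}
    for section in article.sections:
        letter = section.id_letter
        for block in section.subsections:
            sub_idx = sub_counter.get(letter, 0)
            if sub_idx > 99:
                raise CapacityError(
                    f"{article.pmcid}: >100 subsections for section {letter}"
                )
            sub_counter[letter] = sub_idx + 1
            spans = splitter(block)
            if len(spans) > 1000:
                raise CapacityError(
                    f"{article.pmcid}: >1000 sentences in one subsection"
                )
            for sent_idx, (s, e) in enumerate(spans):
                sid = f"{letter}{sub_idx:02d}{sent_idx:03d}"
                sentences.append(
                    Sentence(
                        pmcid=article.pmcid,
                        sentence_id=sid,
                        text=block[s:e],
                        section_group=section.code,
                    )
                )
    return sentences


# ---------------------------------------------------------------------------
# corpus files (sentence text file + 5-field annotation TSV)

_TSV_HEADER = (
    "# pmcid\tsentence_id\tstart\tend\tentity\n"
    "# character offsets are 0-based, end-exclusive\n"
)


def write_corpus_files(
    sentences: Sequence[Sentence],
    annotations: Sequence[AnnotationRecord],
    out_text: str | Path,
    out_tsv: str | Path,
) -> None:
    """Write the corpus sentence file and the 5-field annotation TSV.

    Only sentences with at least one annotation are written to the text
    file.  Raises :class:`CorpusIntegrityError` if an annotation references
    an unknown sentence, and :class:`ValueError` if a sentence text contains
    a tab or newline (unrepresentable in the tab-separated dialect).
    """
    known = {(s.pmcid, s.sentence_id): s for s in sentences}
    annotated: set[tuple[str, str]] = set()
    for ann in annotations:
        ref = (ann.pmcid, ann.sentence_id)
        if ref not in known:
            raise CorpusIntegrityError(
                f"annotation references unknown sentence {ref}"
            )
        sent = known[ref]
        if sent.text[ann.start : ann.end] != ann.entity:
            raise CorpusIntegrityError(
                f"annotation entity mismatch at {ref}: "
                f"{ann.entity!r} != {sent.text[ann.start:ann.end]!r}"
            )
        annotated.add(ref)

    with open(out_text, "w", encoding="utf-8") as fh:
        for s in sentences:
            if (s.pmcid, s.sentence_id) not in annotated:
                continue
            if "\t" in s.text or "\n" in s.text:
                raise ValueError(f"sentence {s.sentence_id} contains tab/newline")
            fh.write(f"{s.pmcid}\t{s.sentence_id}\t{s.text}\n")

    with open(out_tsv, "w", encoding="utf-8") as fh:
        fh.write(_TSV_HEADER)
        for ann in annotations:
            fh.write(
                f"{ann.pmcid}\t{ann.sentence_id}\t{ann.start}\t{ann.end}\t{ann.entity}\n"
            )


def read_corpus_files(
    text_path: str | Path, tsv_path: str | Path
) -> tuple[list[Sentence], list[AnnotationRecord]]:
    """Read the corpus sentence file and annotation TSV back into memory."""
    sentences: list[Sentence] = []
    with open(text_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pmcid, sid, text = line.split("\t", 2)
            sentences.append(Sentence(pmcid=pmcid, sentence_id=sid, text=text))
    annotations: list[AnnotationRecord] = []
    with open(tsv_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"annotation row has {len(fields)} fields, expected 5")
            pmcid, sid, start, end, entity = fields
            annotations.append(
                AnnotationRecord(pmcid, sid, int(start), int(end), entity)
            )
    return sentences, annotations


def check_corpus(
    sentences: Iterable[Sentence], annotations: Iterable[AnnotationRecord]
) -> None:
    """Corpus-wide invariant check: unique sentence keys and entity/substring
    agreement for every annotation."""
    index: dict[tuple[str, str], str] = {}
    for s in sentences:
        key = (s.pmcid, s.sentence_id)
        if key in index:
            raise CorpusIntegrityError(f"duplicate sentence key {key}")
        index[key] = s.text
    for a in annotations:
        key = (a.pmcid, a.sentence_id)
        if key not in index:
            raise CorpusIntegrityError(f"annotation references unknown sentence {key}")
        if index[key][a.start : a.end] != a.entity:
            raise CorpusIntegrityError(f"entity/substring mismatch at {key}")
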