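"""Whole-document annotation: sections, table cells and abbreviations.

Any per-sentence annotator (rule-based pipeline or trained model) is
applied to the filtered A/M/R/D sentences of an article, to every table
cell (each cell treated as a standalone sentence with a table-scoped
identifier outside the A/M/R/D ID space), and to the abbreviation list:
when the *entire* definition of a short form is recognised as one entity —
without any incomplete-entity fixups — every whole-word occurrence of the
short form in the article's sentences becomes an abbreviation-sourced
record.  Sources ("text", "table", "abbreviation") partition the record
set so they can be evaluated separately.
"""

from __future__ import annotations

import html
import re
from typing import Iterable, Protocol, Sequence

from .corpus_io import AnnotationRecord, Article, Sentence, SentenceSplitter, split_and_identify
from .rules import RuleAnnotator, Span


class SentenceAnnotator(Protocol):
    def annotate_sentence(self, sentence: Sentence) -> list[AnnotationRecord]: ...


def table_cell_id(table_idx: int, row_idx: int, col_idx: int) -> str:
    """Synthetic table-scoped sentence ID, e.g. ``T000102`` = table 0, row 1,
    column 2.  Outside the A/M/R/D space and never written to corpus files."""
    return f"T{table_idx:02d}{row_idx:02d}{col_idx:02d}"


def annotate_document(
    article: Article,
    annotator: SentenceAnnotator,
    include_tables: bool = True,
    include_abbreviations: bool = True,
    splitter: SentenceSplitter | None = None,
) -> list[AnnotationRecord]:
    """Annotate an article's sentences, table cells and abbreviations.

    Returns records labelled by source; table-cell records carry synthetic
    table-scoped IDs and character offsets into the cell text.
    """
    records: list[AnnotationRecord] = []
    sentences = split_and_identify(article, splitter)
    for sent in sentences:
        records.extend(annotator.annotate_sentence(sent))

    if include_tables:
        for t_idx, table in enumerate(article.tables):
            for r_idx, row in enumerate(table):
                for c_idx, cell in enumerate(row):
                    cell = cell.strip()
                    if not cell:
                        continue
                    pseudo = Sentence(
                        pmcid=article.pmcid,
                        sentence_id="A00000",  # placeholder; re-keyed below
                        text=cell,
                    )
                    for rec in annotator.annotate_sentence(pseudo):
                        records.append(
                            AnnotationRecord(
                                pmcid=article.pmcid,
                                sentence_id=table_cell_id(t_idx, r_idx, c_idx),
                                start=rec.start,
                                end=rec.end,
                                entity=rec.entity,
                                source="table",
                            )
                        )

    if include_abbreviations and article.abbreviations:
        records.extend(link_abbreviations(article, annotator, sentences))
    return records


def _recognises_whole(annotator: SentenceAnnotator, text: str) -> bool:
    """True iff the raw annotator output covers the entire text as one
    entity, with no incomplete-entity fixups applied."""
    text = text.strip()
    if not text:
        return False
    if isinstance(annotator, RuleAnnotator):
        spans = annotator.match_spans(text)
    elif hasattr(annotator, "predict_raw_spans"):
        spans = annotator.predict_raw_spans(text)
    else:
        # fall back to the annotator's full output; models decode spans
        # before fixups via predict_spans when available
        pseudo = Sentence(pmcid="PMC0", sentence_id="A00000", text=text)
        spans = [Span(r.start, r.end) for r in annotator.annotate_sentence(pseudo)]
    return any(sp.start == 0 and sp.end == len(text) for sp in spans)


def link_abbreviations(
    article: Article,
    annotator: SentenceAnnotator,
    sentences: Sequence[Sentence] | None = None,
    splitter: SentenceSplitter | None = None,
) -> list[AnnotationRecord]:
    """Mark occurrences of short forms whose definition is fully recognised.

    A short form is linked iff its entire definition is recognised as a
    single entity (fixup rules are deliberately not applied to
    definitions).  Matching of the short form in text is case-sensitive and
    whole-word.
    """
    if sentences is None:
        sentences = split_and_identify(article, splitter)
    records: list[AnnotationRecord] = []
    for short, definition in article.abbreviations.items():
        if not short or not _recognises_whole(annotator, definition):
            continue
        pattern = re.compile(r"(?<![A-Za-z0-9])" + re.escape(short) + r"(?![A-Za-z0-9])")
        for sent in sentences:
            for m in pattern.finditer(sent.text):
                records.append(
                    AnnotationRecord(
                        pmcid=sent.pmcid,
                        sentence_id=sent.sentence_id,
                        start=m.start(),
                        end=m.end(),
                        entity=m.group(0),
                        source="abbreviation",
                    )
                )
    return records


def records_by_source(
    records: Iterable[AnnotationRecord],
) -> dict[str, list[AnnotationRecord]]:
    out: dict[str, list[AnnotationRecord]] = {}
    for r in records:
        out.setdefault(r.source, []).append(r)
    return out


_MARK_COLOURS = {"both": "#8f8", "model": "#ff8", "rule": "#f88"}


def annotated_html(
    sentences: Sequence[Sentence],
    records_a: Sequence[AnnotationRecord],
    records_b: Sequence[AnnotationRecord] | None = None,
) -> str:
    """Minimal HTML export with colour-coded marks: green = found by both
    annotators, yellow = only the first, red = only the second."""
    b_keys = {r.key for r in records_b} if records_b is not None else set()
    a_keys = {r.key for r in records_a}
    by_sentence: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for key in a_keys | b_keys:
        cat = "both" if key in a_keys and key in b_keys else ("model" if key in a_keys else "rule")
        by_sentence.setdefault((key[0], key[1]), []).append((key[2], key[3], cat))
    parts = ["<html><body>"]
    for s in sentences:
        spans = sorted(by_sentence.get((s.pmcid, s.sentence_id), []))
        cursor = 0
        buf = [f"<p><b>{s.pmcid} {s.sentence_id}</b> "]
        for start, end, cat in spans:
            if start < cursor:
                continue
            buf.append(html.escape(s.text[cursor:start]))
            buf.append(
                f'<mark style="background:{_MARK_COLOURS[cat]}">'
                f"{html.escape(s.text[start:end])}</mark>"
            )
            cursor = end
        buf.append(html.escape(s.text[cursor:]))
        buf.append("</p>")
        parts.append("".join(buf))
    parts.append("</body></html>")
    return "\n".join(parts)
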