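"""Span-level evaluation and corpus summary statistics.

Matching is exact by default: a predicted annotation is a true positive iff
its (pmcid, sentence_id, start, end) key appears in the gold set.  Scores
are precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2pr/(p+r) and the
F*-score pr/(p+r-pr), which is never larger than F1.  Abbreviation- and
table-sourced records are evaluated separately from text records, so the
source filter applies to both sides of a comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import AnnotationRecord, Sentence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    fstar: float
    degenerate: bool = False

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Report-style rounding (half-even, like the builtin)."""
        return {
            "precision": round(self.precision, ndigits),
            "recall": round(self.recall, ndigits),
            "f1": round(self.f1, ndigits),
            "fstar": round(self.fstar, ndigits),
        }


def f1_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def fstar_score(precision: float, recall: float) -> float:
    """F* = pr/(p+r-pr); equals F1 only at p=r=1, otherwise smaller."""
    denom = precision + recall - precision * recall
    if denom == 0:
        return 0.0
    return precision * recall / denom


def score(tp: int, fp: int, fn: int) -> EvalResult:
    """All four measures from raw counts; degenerate denominators score 0
    and set the ``degenerate`` flag."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        fstar=fstar_score(precision, recall),
        degenerate=degenerate,
    )


def score_from_rates(precision: float, recall: float) -> EvalResult:
    """F1/F* from already-computed precision and recall (e.g. a published
    results table)."""
    return EvalResult(
        tp=0,
        fp=0,
        fn=0,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        fstar=fstar_score(precision, recall),
        degenerate=False,
    )


def _dedup(records: Iterable[AnnotationRecord], side: str) -> dict:
    out = {}
    dups = 0
    for r in records:
        if r.key in out:
            dups += 1
        out[r.key] = r
    if dups:
        logger.warning("%d duplicate annotation keys in %s set", dups, side)
    return out


def match_annotations(
    pred: Sequence[AnnotationRecord],
    gold: Sequence[AnnotationRecord],
    mode: str = "exact",
    include_sources: Iterable[str] = ("text",),
) -> tuple[int, int, int]:
    """(tp, fp, fn) under exact-key matching with a source filter applied to
    both sides.

    ``mode="overlap"`` grants a predicted record credit when it overlaps any
    gold record in the same sentence (never used for headline scores).
    """
    sources = set(include_sources)
    p = _dedup((r for r in pred if r.source in sources), "pred")
    g = _dedup((r for r in gold if r.source in sources), "gold")
    if mode == "exact":
        tp = len(p.keys() & g.keys())
        return tp, len(p) - tp, len(g) - tp
    if mode != "overlap":
        raise ValueError(f"unknown mode {mode!r}")
    matched_gold: set = set()
    tp = 0
    for key, r in p.items():
        hit = None
        for gk, gr in g.items():
            if gk in matched_gold:
                continue
            if gr.pmcid == r.pmcid and gr.sentence_id == r.sentence_id:
                if r.start < gr.end and gr.start < r.end:
                    hit = gk
                    break
        if hit is not None:
            matched_gold.add(hit)
            tp += 1
    return tp, len(p) - tp, len(g) - len(matched_gold)


def evaluate(
    pred: Sequence[AnnotationRecord],
    gold: Sequence[AnnotationRecord],
    mode: str = "exact",
    include_sources: Iterable[str] = ("text",),
) -> EvalResult:
    return score(*match_annotations(pred, gold, mode, include_sources))


def per_section_metrics(
    pred: Sequence[AnnotationRecord],
    gold: Sequence[AnnotationRecord],
    sentences: Sequence[Sentence],
    include_sources: Iterable[str] = ("text",),
) -> dict[str, EvalResult]:
    """Scores per section group (A/M/R/RD/D), partitioning records by the
    group of the sentence they reference."""
    group_of = {(s.pmcid, s.sentence_id): s.section_group for s in sentences}
    sources = set(include_sources)

    def partition(records):
        parts: dict[str, list[AnnotationRecord]] = {}
        for r in records:
            if r.source not in sources:
                continue
            key = (r.pmcid, r.sentence_id)
            if key not in group_of:
                raise ValueError(f"record references unknown sentence {key}")
            parts.setdefault(group_of[key], []).append(r)
        return parts

    pparts = partition(pred)
    gparts = partition(gold)
    return {
        grp: score(
            *match_annotations(
                pparts.get(grp, []), gparts.get(grp, []), include_sources=sources
            )
        )
        for grp in sorted(set(pparts) | set(gparts))
    }


def corpus_stats(
    annotations_by_article: Mapping[str, Iterable[str]],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group summary: total unique-per-article metabolite count, number
    of articles, and mean unique metabolites per article (1 decimal place).

    Uniqueness is per (article, case-folded entity): a metabolite mentioned
    ten times in one article counts once for that article.
    """
    rows = []
    groups: dict[str, list[str]] = {}
    for pmcid in annotations_by_article:
        grp = grouping.get(pmcid, "all") if grouping else "all"
        groups.setdefault(grp, []).append(pmcid)
    for grp in sorted(groups):
        pmcids = groups[grp]
        counts = [
            len({e.casefold() for e in annotations_by_article[p]}) for p in pmcids
        ]
        total = sum(counts)
        n = len(pmcids)
        rows.append(
            {
                "group": grp,
                "n_unique_metabolites": total,
                "n_articles": n,
                "mean_unique_per_article": round(total / n, 1) if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("group")
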