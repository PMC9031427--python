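"""Deterministic synthetic fixtures: dictionaries, corpora, word vectors.

Everything a test or example needs — toy metabolite dictionaries built
from metabolite-like morphemes, articles with A/M/R/D sections, tables and
defined abbreviations, gold annotations recorded at plant time, optional
single-character typos, and word-vector files — is generated here, fully
determined by a seed.  The sentence templates deliberately use a scaffold
vocabulary that no shipped regex pattern matches, so planted gold spans
are exactly what the rule pipeline should recover at typo rate 0.

What this emulates: the *structure* of a standardised full-text corpus
(section codes, sentence IDs, tables, abbreviation maps) and its annotation
error modes (spelling errors, undefined abbreviations).  What it does not:
linguistic realism, citation sections, encoding artefacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import AnnotationRecord, Article, Section, Sentence

# ---------------------------------------------------------------------------
# dictionary generation

_STEMS = [
    "gluc", "fruct", "galact", "lact", "citr", "pyruv", "malon", "fumar",
    "succin", "palmit", "stear", "linole", "arachid", "xanth", "hippur",
    "taur", "creatin", "adenos", "guanos", "cytid", "urid", "sorbit",
    "threon", "glycer", "alanin", "valer", "leucin", "prolin", "tyros",
    "cystin", "aspart", "glutam", "ornith", "carnos", "betain", "spermid",
    "putresc", "cadaver", "kynuren", "seroton", "cholester", "bilirub",
]
_SUFFIXES = ["ate", "ose", "ine", "ol", "itol", "amine"]
_LIPID_CLASSES = ["PC", "PE", "SM", "LPC", "TG", "CE"]
_ACID_STEMS = [
    "citric", "palmitic", "stearic", "oleic", "linoleic", "succinic",
    "fumaric", "malic", "lactic", "pyruvic", "hippuric", "uric", "folic",
    "glutamic", "aspartic", "kynurenic",
]


def make_dictionary(
    n_names: int,
    seed: int = 0,
    n_expected: int = 0,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Generate a metabolite-like dictionary of ``n_names`` entries.

    Returns the dictionary table (columns name, synonyms, status) and the
    name list.  Always contains at least one multiword and one bracketed
    name (for n >= 3); ``n_expected`` entries get status ``expected`` (the
    rest alternate quantified/detected).  Deterministic per seed; all
    generated names survive default cleaning (length > 5, not blocklisted).
    """
    if n_names < 1:
        raise ValueError("n_names must be >= 1")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    seen: set[str] = set()

    def add(name: str) -> None:
        if name.casefold() not in seen and len(name) > 5:
            seen.add(name.casefold())
            names.append(name)

    if n_names >= 2:
        add(_ACID_STEMS[rng.integers(len(_ACID_STEMS))] + " acid")
    if n_names >= 3:
        cls = _LIPID_CLASSES[rng.integers(len(_LIPID_CLASSES))]
        a, b = rng.integers(14, 23), rng.integers(0, 7)
        c, d = rng.integers(14, 23), rng.integers(0, 7)
        add(f"{cls}({a}:{b}/{c}:{d})")
    guard = 0
    while len(names) < n_names and guard < 10000:
        guard += 1
        kind = rng.integers(0, 10)
        if kind < 6:
            stem = _STEMS[rng.integers(len(_STEMS))]
            add(stem + _SUFFIXES[rng.integers(len(_SUFFIXES))])
        elif kind < 7:
            add(_ACID_STEMS[rng.integers(len(_ACID_STEMS))] + " acid")
        elif kind < 8:
            locant = int(rng.integers(2, 6))
            stem = _STEMS[rng.integers(len(_STEMS))]
            add(f"{locant}-hydroxy{stem}{_SUFFIXES[rng.integers(3)]}")
        else:
            cls = _LIPID_CLASSES[rng.integers(len(_LIPID_CLASSES))]
            a, b = rng.integers(14, 23), rng.integers(0, 7)
            add(f"{cls}({a}:{b})")
    names = names[:n_names]

    statuses = []
    expected_idx = set(rng.choice(len(names), size=min(n_expected, len(names)), replace=False).tolist())
    for i in range(len(names)):
        if i in expected_idx:
            statuses.append("expected")
        else:
            statuses.append("quantified" if i % 2 == 0 else "detected")
    synonyms = []
    for i, name in enumerate(names):
        if " " not in name and "(" not in name and i % 7 == 3:
            synonyms.append(f"L-{name}")
        else:
            synonyms.append("")
    df = pd.DataFrame({"name": names, "synonyms": synonyms, "status": statuses})
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df, names


def corrupt_name(name: str, rng: np.random.Generator) -> str:
    """A single-character interior deletion or substitution of ``name``."""
    core = [i for i, ch in enumerate(name) if ch.isalpha()]
    core = [i for i in core if 1 <= i < len(name) - 1]
    if not core:
        return name
    pos = int(core[rng.integers(len(core))])
    if rng.random() < 0.5 and len(name) > 6:
        return name[:pos] + name[pos + 1 :]
    letters = "abcdefghijklmnopqrstuvwxyz"
    repl = letters[rng.integers(26)]
    while repl == name[pos].lower():
        repl = letters[rng.integers(26)]
    return name[:pos] + repl + name[pos + 1 :]


# ---------------------------------------------------------------------------
# corpus generation

# scaffold vocabulary checked against the default pattern set: no pattern
# matches any of these words, so gold spans stay exactly as planted
_TEMPLATES: dict[str, list[str]] = {
    "A": [
        "We measured {m} and {m} in blood from affected individuals.",
        "Levels of {m} were higher in cases compared with controls.",
        "This study shows that {m} is a possible marker for disease.",
    ],
    "M": [
        "Samples were analysed using standard protocols for {m} and {m}.",
        "Calibration was performed with {m} as internal standard.",
        "All subjects provided consent and blood was collected at the clinic.",
    ],
    "R": [
        "We observed significant changes in {m} and {m} between groups.",
        "The level of {m} was lower in the disease group.",
        "Differences in {m} remained significant after adjustment.",
    ],
    "D": [
        "Our findings for {m} agree with previous reports.",
        "The observed shift in {m} and {m} suggests altered energy turnover.",
        "Further work is needed to confirm the role of {m} in this disease.",
    ],
}

_IAO_TERMS = {
    "A": "textual abstract section",
    "M": "methods section",
    "R": "results section",
    "D": "discussion section",
    "RD": "results and discussion section",
}


@dataclass
class CorpusFixture:
    """A generated corpus with its ground truth."""

    articles: list[Article]
    sentences: list[Sentence]
    gold: list[AnnotationRecord] = field(default_factory=list)
    typo_gold: list[AnnotationRecord] = field(default_factory=list)

    @property
    def all_gold(self) -> list[AnnotationRecord]:
        return self.gold + self.typo_gold


def _fill_template(
    template: str,
    names: Sequence[str],
    rng: np.random.Generator,
    typo_rate: float,
) -> tuple[str, list[tuple[int, int, bool]]]:
    """Substitute {m} slots; returns text and (start, end, is_typo) spans."""
    parts = template.split("{m}")
    text = parts[0]
    spans: list[tuple[int, int, bool]] = []
    for tail in parts[1:]:
        name = names[rng.integers(len(names))]
        is_typo = typo_rate > 0 and rng.random() < typo_rate
        surface = corrupt_name(name, rng) if is_typo else name
        start = len(text)
        text += surface
        spans.append((start, start + len(surface), is_typo))
        text += tail
    return text, spans


def make_corpus(
    n_articles: int,
    names: Sequence[str],
    typo_rate: float = 0.0,
    abbrev_rate: float = 0.3,
    table_rate: float = 0.7,
    rd_rate: float = 0.25,
    seed: int = 0,
    sentences_per_subsection: tuple[int, int] = (2, 4),
) -> CorpusFixture:
    """Generate ``n_articles`` articles with planted metabolite mentions.

    Every article has A/M/R/D sections (or A/M/RD with probability
    ``rd_rate``), each section 1-2 subsections of 2-4 template sentences;
    with the given probabilities it also gets a table with metabolite cells
    and a defined abbreviation whose definition is a multiword dictionary
    name.  Gold spans are recorded at plant time; typo'd mentions are
    returned separately so exact-match and generalisation recall can be
    told apart.  Byte-identical output for a fixed seed.
    """
    if not names:
        raise ValueError("empty name list")
    if not (0 <= typo_rate <= 1 and 0 <= abbrev_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    multiword = [n for n in names if " " in n]
    articles: list[Article] = []
    sentences: list[Sentence] = []
    gold: list[AnnotationRecord] = []
    typo_gold: list[AnnotationRecord] = []

    for a_idx in range(n_articles):
        pmcid = f"PMC{7000000 + a_idx}"
        combined_rd = rng.random() < rd_rate
        section_plan = ["A", "M", "RD"] if combined_rd else ["A", "M", "R", "D"]
        art_sections: list[Section] = []
        sub_counter: dict[str, int] = {}
        for code in section_plan:
            letter = "R" if code == "RD" else code
            templates = _TEMPLATES[letter if letter in _TEMPLATES else "R"]
            if code == "RD":
                templates = _TEMPLATES["R"] + _TEMPLATES["D"]
            n_subs = int(rng.integers(1, 3))
            blocks: list[str] = []
            for _ in range(n_subs):
                sub_idx = sub_counter.get(letter, 0)
                sub_counter[letter] = sub_idx + 1
                lo, hi = sentences_per_subsection
                n_sent = int(rng.integers(lo, hi + 1))
                sent_texts: list[str] = []
                for s_idx in range(n_sent):
                    tmpl = templates[rng.integers(len(templates))]
                    text, spans = _fill_template(tmpl, names, rng, typo_rate)
                    sid = f"{letter}{sub_idx:02d}{s_idx:03d}"
                    sentences.append(
                        Sentence(pmcid=pmcid, sentence_id=sid, text=text,
                                 section_group=code)
                    )
                    for start, end, is_typo in spans:
                        rec = AnnotationRecord(
                            pmcid=pmcid, sentence_id=sid,
                            start=start, end=end, entity=text[start:end],
                        )
                        (typo_gold if is_typo else gold).append(rec)
                    sent_texts.append(text)
                blocks.append(" ".join(sent_texts))
            art_sections.append(
                Section(code=code, iao_term=_IAO_TERMS[code], subsections=blocks)
            )

        tables: list[list[list[str]]] = []
        if rng.random() < table_rate:
            n_rows = int(rng.integers(2, 5))
            rows = [["Metabolite", "Direction"]]
            for _ in range(n_rows):
                rows.append(
                    [
                        names[rng.integers(len(names))],
                        "up" if rng.random() < 0.5 else "down",
                    ]
                )
            tables.append(rows)

        abbreviations: dict[str, str] = {}
        if multiword and rng.random() < abbrev_rate:
            definition = multiword[rng.integers(len(multiword))]
            short = "".join(w[0].upper() for w in definition.split())
            abbreviations[short] = definition

        articles.append(
            Article(
                pmcid=pmcid,
                sections=art_sections,
                tables=tables,
                abbreviations=abbreviations,
            )
        )
    return CorpusFixture(
        articles=articles, sentences=sentences, gold=gold, typo_gold=typo_gold
    )


def template_vocabulary() -> list[str]:
    """All scaffold words used by the sentence templates (negative-lexicon
    material for the preclassifier)."""
    words: set[str] = set()
    for templates in _TEMPLATES.values():
        for t in templates:
            for w in t.replace("{m}", " ").replace(".", " ").replace(",", " ").split():
                words.add(w)
                words.add(w.lower())
    return sorted(words)


# ---------------------------------------------------------------------------
# file emission


def write_article_json(
    article: Article,
    out_dir: str | Path,
    include_introduction: bool = True,
) -> dict[str, Path]:
    """Emit maintext/table/abbreviation JSON files for one article in the
    dialect the corpus reader consumes.  An introduction paragraph is
    included by default to exercise section filtering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paragraphs = []
    if include_introduction:
        paragraphs.append(
            {
                "section_heading": "Introduction",
                "subsection_heading": "",
                "body": "Reviewing the growing literature is hard work.",
                "IAO_term": "introduction section",
                "IAO_ID": "IAO:0000316",
            }
        )
    for section in article.sections:
        for block in section.subsections:
            paragraphs.append(
                {
                    "section_heading": section.code,
                    "subsection_heading": "",
                    "body": block,
                    "IAO_term": section.iao_term,
                    "IAO_ID": "",
                }
            )
    paths = {}
    maintext = out_dir / f"{article.pmcid}_maintext.json"
    maintext.write_text(
        json.dumps({"pmcid": article.pmcid, "paragraphs": paragraphs}, indent=1),
        "utf-8",
    )
    paths["maintext"] = maintext
    if article.tables:
        tpath = out_dir / f"{article.pmcid}_tables.json"
        tpath.write_text(
            json.dumps({"tables": [{"rows": t} for t in article.tables]}, indent=1),
            "utf-8",
        )
        paths["table"] = tpath
    if article.abbreviations:
        apath = out_dir / f"{article.pmcid}_abbreviations.json"
        apath.write_text(
            json.dumps({"abbreviations": article.abbreviations}, indent=1), "utf-8"
        )
        paths["abbreviation"] = apath
    return paths


def make_wordvec_file(
    vocab: Sequence[str],
    dim: int,
    seed: int,
    out_path: str | Path,
) -> Path:
    """Write a text word-vector file: one ``token v1 ... vdim`` line per
    token, values from a seeded standard normal."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)
    with open(out_path, "w", encoding="utf-8") as fh:
        for token in vocab:
            vec = rng.standard_normal(dim)
            fh.write(token + " " + " ".join(f"{v:.4f}" for v in vec) + "\n")
    return out_path


def corpus_vocabulary(names: Sequence[str]) -> list[str]:
    """Scaffold vocabulary plus all tokens of the given names (chem-word
    tokenisation), for building word-vector files."""
    from .tagging import tokenize

    vocab: set[str] = set(template_vocabulary())
    for name in names:
        for tok in tokenize(name):
            vocab.add(tok.text)
    return sorted(vocab)
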