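"""Metabolite name dictionaries and the regex reference set.

A dictionary is a flat set of surface strings (names and synonyms) with a
curation status per entry — ``quantified``, ``detected``, ``expected`` or
``predicted`` — mirroring metabolome-database conventions.  By default only
``quantified``/``detected`` entries are loaded.  Cleaning removes short,
ambiguous entries (length <= 5 unless whitelisted) and a user-replaceable
blocklist of common-word synonyms (e.g. "result", a synonym of omeprazole).

The *reference set* is the subset of entries containing a space, hyphen or
colon: the less trivial names used to craft and measure coverage of the
regular-expression pattern set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STATUSES = frozenset({"quantified", "detected", "expected", "predicted"})
DEFAULT_STATUSES = frozenset({"quantified", "detected"})

_SYNONYM_SEP = re.compile(r"[|;]")


@dataclass
class MetaboliteDictionary:
    """A cleaned set of metabolite surface names with status metadata."""

    entries: set[str] = field(default_factory=set)
    status: dict[str, str] = field(default_factory=dict)
    removed: list[tuple[str, str]] = field(default_factory=list)  # (entry, reason)

    @property
    def normalised_index(self) -> dict[str, set[str]]:
        """Case-folded entry -> original-case entries."""
        idx: dict[str, set[str]] = {}
        for e in self.entries:
            idx.setdefault(e.casefold(), set()).add(e)
        return idx

    def folded_entries(self) -> set[str]:
        return {e.casefold() for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name.casefold() in self.normalised_index


@dataclass(frozen=True)
class ReferenceSet:
    """Dictionary entries containing at least one space, hyphen or colon."""

    terms: frozenset[str]

    def __len__(self) -> int:
        return len(self.terms)


def load_dictionary(
    path: str | Path,
    statuses: Iterable[str] = DEFAULT_STATUSES,
) -> MetaboliteDictionary:
    """Load a name/synonym dictionary file, keeping the given statuses.

    The file is CSV or TSV (autodetected) with columns ``name``,
    ``synonyms`` (optional, '|' or ';' separated) and ``status``.  Synonyms
    are expanded into entries of their own, inheriting the name's status.
    """
    statuses = {s.lower() for s in statuses}
    unknown = statuses - STATUSES
    if unknown:
        raise ValueError(f"unknown statuses {sorted(unknown)}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else None
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "status" not in df.columns or "name" not in df.columns:
        missing = {"name", "status"} - set(df.columns)
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    d = MetaboliteDictionary()
    for _, row in df.iterrows():
        status = row["status"].strip().lower()
        if status not in statuses:
            continue
        names = [row["name"].strip()]
        if "synonyms" in df.columns and row["synonyms"].strip():
            names.extend(
                s.strip() for s in _SYNONYM_SEP.split(row["synonyms"]) if s.strip()
            )
        for name in names:
            if name:
                d.entries.add(name)
                d.status[name] = status
    if not d.entries:
        logger.warning("%s: no entries with statuses %s", path, sorted(statuses))
    return d


def clean_dictionary(
    d: MetaboliteDictionary,
    blocklist: Iterable[str] | None = None,
    whitelist: Iterable[str] | None = None,
    max_ambig_len: int = 5,
) -> MetaboliteDictionary:
    """Remove short ambiguous entries and blocklisted common words.

    Entries of length <= ``max_ambig_len`` are removed unless their
    case-folded form is whitelisted; blocklisted entries are removed
    regardless of length.  Idempotent; removals are logged on the returned
    dictionary.
    """
    block = {b.casefold() for b in (blocklist if blocklist is not None else default_blocklist())}
    white = {w.casefold() for w in (whitelist if whitelist is not None else default_whitelist())}
    out = MetaboliteDictionary(removed=list(d.removed))
    for e in sorted(d.entries):
        folded = e.casefold()
        if folded in block:
            out.removed.append((e, "blocklist"))
        elif len(e) <= max_ambig_len and folded not in white:
            out.removed.append((e, "short-ambiguous"))
        else:
            out.entries.add(e)
            out.status[e] = d.status.get(e, "detected")
    return out


def build_reference_set(d: MetaboliteDictionary) -> ReferenceSet:
    """Entries containing one or more of space, ``-`` or ``:``."""
    return ReferenceSet(
        terms=frozenset(
            e for e in d.entries if any(ch in e for ch in (" ", "-", ":"))
        )
    )


def pattern_coverage(
    patterns: Sequence[str],
    reference_set: ReferenceSet,
) -> tuple[float, list[str]]:
    """Fraction of reference-set terms with a partial match from >=1 pattern.

    Returns ``(coverage, uncovered_terms)``; the uncovered terms feed the
    recursive pattern-crafting workflow (inspect, add or widen a pattern,
    re-measure).  Raises ``re.error`` naming the offending pattern when one
    does not compile.
    """
    compiled = []
    for p in patterns:
        try:
            compiled.append(re.compile(p))
        except re.error as exc:
            raise re.error(f"pattern {p!r} does not compile: {exc}") from exc
    if not reference_set.terms:
        return 1.0, []
    uncovered = sorted(
        t for t in reference_set.terms if not any(c.search(t) for c in compiled)
    )
    covered = len(reference_set.terms) - len(uncovered)
    return covered / len(reference_set.terms), uncovered


# ---------------------------------------------------------------------------
# shipped word lists


def _read_list(name: str) -> list[str]:
    text = resources.files("metanner").joinpath("data", name).read_text("utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def default_blocklist() -> list[str]:
    """Starter blocklist of common-word metabolite synonyms."""
    return _read_list("blocklist.txt")


def default_whitelist() -> list[str]:
    """Short strings that are metabolite-exclusive enough to keep."""
    return _read_list("whitelist.txt")


def default_stopwords() -> list[str]:
    return _read_list("stopwords.txt")
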