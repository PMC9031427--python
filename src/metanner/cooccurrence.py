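"""Article-weighted metabolite co-occurrence networks.

Nodes are (case-folded) metabolite surface names weighted by the number of
articles mentioning them; an edge between two metabolites is weighted by
the number of articles mentioning both (once per article, regardless of
how often the pair co-occurs within it).  The node attribute
``top_article`` records the article reporting the metabolite most often
(ties broken by the lexicographically lower article ID) — used downstream
for colouring.  Layout and rendering are left to external graph tools; the
exports (weighted adjacency TSV and GEXF) carry everything they need.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


def build_graph(per_article_entities: Mapping[str, Iterable[str]]) -> nx.Graph:
    """Build the co-occurrence graph from per-article entity mentions.

    Entities are case-folded; repeats within an article count once for
    node/edge weights but inform the ``top_article`` attribute.
    """
    g = nx.Graph()
    mention_counts: dict[str, Counter] = {}
    for pmcid, entities in per_article_entities.items():
        folded = [e.casefold() for e in entities]
        for name in folded:
            mention_counts.setdefault(name, Counter())[pmcid] += 1
        unique = sorted(set(folded))
        for name in unique:
            if g.has_node(name):
                g.nodes[name]["weight"] += 1
            else:
                g.add_node(name, weight=1)
        for a, b in combinations(unique, 2):
            if g.has_edge(a, b):
                g.edges[a, b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    for name, counts in mention_counts.items():
        # most-reporting article; ties -> lower article ID
        top = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        g.nodes[name]["top_article"] = top
    return g


def filter_min_articles(g: nx.Graph, k: int) -> nx.Graph:
    """Drop nodes reported by fewer than ``k`` articles (k=1 is identity);
    incident edges go with them.  Idempotent and monotone in k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = [n for n, data in g.nodes(data=True) if data["weight"] >= k]
    return g.subgraph(keep).copy()


def top_metabolites(
    per_article_entities: Mapping[str, Iterable[str]],
    n: int = 10,
) -> pd.DataFrame:
    """The ``n`` metabolites reported by the most articles, with the
    percentage of articles reporting each (rounded to whole percent)."""
    total = len(per_article_entities)
    counts: Counter = Counter()
    for entities in per_article_entities.values():
        counts.update({e.casefold() for e in entities})
    rows = [
        {
            "name": name,
            "n_articles": cnt,
            "percent": round(100 * cnt / total) if total else 0,
        }
        for name, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    ]
    return pd.DataFrame(rows, columns=["name", "n_articles", "percent"])


def export_adjacency_tsv(g: nx.Graph, path: str | Path) -> None:
    """Weighted adjacency list: source, target, weight (tab-separated)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']}\n")


def export_gexf(g: nx.Graph, path: str | Path) -> None:
    nx.write_gexf(g, path)


def records_to_per_article(
    records,
    sections: Iterable[str] = ("A", "R", "RD", "D"),
    sentences=None,
) -> dict[str, set[str]]:
    """Group annotation records into per-article entity sets.

    By default only abstract/results (incl. tables)/discussion feed the
    graph; table records (IDs starting ``T``) are treated as results.  When
    ``sentences`` is given, section groups come from them; otherwise the
    sentence-ID letter is used.
    """
    wanted = set(sections)
    group_of = (
        {(s.pmcid, s.sentence_id): s.section_group for s in sentences}
        if sentences is not None
        else None
    )
    out: dict[str, set[str]] = {}
    for r in records:
        if r.sentence_id.startswith("T"):
            grp = "R"
        elif group_of is not None:
            grp = group_of.get((r.pmcid, r.sentence_id), r.sentence_id[0])
        else:
            grp = r.sentence_id[0]
        if grp not in wanted:
            continue
        out.setdefault(r.pmcid, set()).add(r.entity.casefold())
    return out
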