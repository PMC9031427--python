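"""Build a metabolite co-occurrence network from annotations.

Annotates a synthetic corpus, groups entities per article (abstract,
results including tables, and discussion sections only), and builds the
article-weighted graph: node weight = number of articles reporting the
metabolite, edge weight = number of articles reporting both endpoints.
Prints the most-reported metabolites with the percentage of articles
mentioning each, filters the graph to metabolites seen in >= 3 articles,
and exports a weighted adjacency list any graph tool can lay out.
"""

from metanner import RuleAnnotator, build_graph, filter_min_articles, top_metabolites
from metanner.cooccurrence import export_adjacency_tsv, records_to_per_article
from metanner.dictionary import MetaboliteDictionary
from metanner.synthetic import make_corpus, make_dictionary

_, names = make_dictionary(30, seed=7)
annotator = RuleAnnotator(MetaboliteDictionary(entries=set(names)))
fixture = make_corpus(40, names, seed=15)

records = []
for sentence in fixture.sentences:
    records.extend(annotator.annotate_sentence(sentence))
per_article = records_to_per_article(records)

print("top reported metabolites (articles, % of corpus):")
print(top_metabolites(per_article, n=5).to_string(index=False))

graph = build_graph(per_article)
core = filter_min_articles(graph, 3)
print(f"\nfull graph: {graph.number_of_nodes()} nodes / {graph.number_of_edges()} edges")
print(f">=3-article core: {core.number_of_nodes()} nodes / {core.number_of_edges()} edges")

export_adjacency_tsv(core, "cooccurrence.tsv")
print("wrote cooccurrence.tsv (source, target, article-count weight)")
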