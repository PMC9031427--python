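"""Whole-document annotation from article JSON files.

Emits one article as maintext/table/abbreviation JSON (the standardised
BioC-style dialect), reads it back with section filtering (introductions
dropped, A/M/R/D kept), and annotates text sentences, table cells and
abbreviation occurrences.  Records are grouped by source because the
three kinds are evaluated separately.
"""

import tempfile
from pathlib import Path

from metanner import RuleAnnotator, read_article
from metanner.dictionary import MetaboliteDictionary
from metanner.document import annotate_document, records_by_source
from metanner.synthetic import make_corpus, make_dictionary, write_article_json

_, names = make_dictionary(30, seed=7)
fixture = make_corpus(5, names, abbrev_rate=1.0, table_rate=1.0, seed=4)
annotator = RuleAnnotator(MetaboliteDictionary(entries=set(names)))

with tempfile.TemporaryDirectory() as tmp:
    paths = write_article_json(fixture.articles[0], Path(tmp))
    article = read_article(
        paths["maintext"], paths.get("table"), paths.get("abbreviation")
    )
    print(f"{article.pmcid}: sections {[s.code for s in article.sections]}, "
          f"{len(article.tables)} table(s), abbreviations {article.abbreviations}")
    records = annotate_document(article, annotator)

for source, recs in records_by_source(records).items():
    print(f"\n{source} ({len(recs)} records):")
    for rec in recs[:5]:
        print(f"  {rec.sentence_id} [{rec.start},{rec.end}) {rec.entity}")
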