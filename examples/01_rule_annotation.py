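"""Annotate sentences with the rule-based pipeline.

Builds a 30-name synthetic dictionary and a small article set, runs the
dictionary + regex + fixup pipeline over every sentence, and writes the
two corpus files (annotated-sentence text file and 5-field annotation
TSV).  The printed records show (sentence ID, [start, end), entity): each
entity is exactly the sentence substring at those 0-based, end-exclusive
offsets.
"""

from metanner import RuleAnnotator, write_corpus_files
from metanner.dictionary import MetaboliteDictionary
from metanner.synthetic import make_corpus, make_dictionary

_, names = make_dictionary(30, seed=7)
dictionary = MetaboliteDictionary(entries=set(names))
annotator = RuleAnnotator(dictionary)

fixture = make_corpus(3, names, seed=1)
records = []
for sentence in fixture.sentences:
    records.extend(annotator.annotate_sentence(sentence))

for rec in records[:10]:
    print(f"{rec.pmcid} {rec.sentence_id} [{rec.start:3d},{rec.end:3d}) {rec.entity}")
print(f"... {len(records)} annotations over {len(fixture.sentences)} sentences")

write_corpus_files(fixture.sentences, records, "corpus.txt", "annotations.tsv")
print("wrote corpus.txt (annotated sentences) and annotations.tsv (5 fields)")
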