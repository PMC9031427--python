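"""Generate the synthetic fixture files every other example consumes.

Writes a dictionary TSV (name/synonyms/status), per-article BioC-style
JSON files, and a 300-d word-vector text file — all fully determined by
the seeds, so re-running reproduces them byte for byte.
"""

from pathlib import Path

from metanner.synthetic import (
    corpus_vocabulary,
    make_corpus,
    make_dictionary,
    make_wordvec_file,
    write_article_json,
)

out = Path("fixtures")
out.mkdir(exist_ok=True)

df, names = make_dictionary(30, seed=7, n_expected=5, out_path=out / "dictionary.tsv")
print(f"dictionary.tsv: {len(df)} entries "
      f"({(df.status == 'expected').sum()} 'expected', dropped at default load)")

fixture = make_corpus(5, names, abbrev_rate=0.5, seed=7)
for article in fixture.articles:
    write_article_json(article, out / "articles")
print(f"articles/: {len(fixture.articles)} articles, "
      f"{len(fixture.sentences)} sentences, {len(fixture.gold)} gold spans")

make_wordvec_file(corpus_vocabulary(names), 300, 7, out / "vectors300.txt")
print("vectors300.txt: one '<token> v1 ... v300' line per vocabulary token")
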