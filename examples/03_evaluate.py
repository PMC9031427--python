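"""Span-level evaluation: precision, recall, F1 and F*.

Runs the rule pipeline over a synthetic corpus with plant-time gold spans
and scores it with exact span matching, globally and per section group
(A/M/R/RD/D).  F* = pr/(p+r-pr) is always at most F1; both are printed to
4 decimal places, the convention for reporting these measures.
"""

from metanner import RuleAnnotator, evaluate, per_section_metrics
from metanner.dictionary import MetaboliteDictionary
from metanner.synthetic import make_corpus, make_dictionary

_, names = make_dictionary(30, seed=7)
annotator = RuleAnnotator(MetaboliteDictionary(entries=set(names)))
fixture = make_corpus(25, names, typo_rate=0.1, seed=9)

pred = []
for sentence in fixture.sentences:
    pred.extend(annotator.annotate_sentence(sentence))

# typo'd mentions are part of the gold standard here, so recall < 1
gold = fixture.all_gold
result = evaluate(pred, gold)
print(f"tp={result.tp} fp={result.fp} fn={result.fn}")
for k, v in result.rounded().items():
    print(f"{k:9s} {v:.4f}")

print("\nper section group:")
for group, res in per_section_metrics(pred, gold, fixture.sentences).items():
    print(f"  {group:2s} P={res.precision:.3f} R={res.recall:.3f} F1={res.f1:.3f}")
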