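# Methods

`metanner` locates metabolite names as character spans in full-text
biomedical articles. It provides two interchangeable annotators — a
rule-based pipeline and a learned sequence tagger — plus the evaluation,
document-application and network-summary machinery around them. This note
records the models, the defaults and why, and what the synthetic test
surface does and does not establish.

## Corpus model

Articles arrive as standardised BioC-style JSON (maintext, table and
abbreviation files per article). Maintext paragraphs carry an IAO section
term; only textual abstract (A), methods (M), results (R) and discussion
(D) sections are used — introductions are dropped because they rarely
describe the study's own measurements. Combined results-and-discussion
sections are kept as group `RD`: they share the `R` letter in sentence
identifiers (the ID alphabet has four letters) but retain their own group
for per-section evaluation.

Sentences are identified as `<letter><2-digit subsection><3-digit
sentence>`, all indices 0-based (`M01001` = second sentence, second
methods subsection). The digit split is a convention of this package
(only "one letter + five digits, 0-based" is fixed by the corpus format)
and is configurable in principle via the capacity limits it implies
(100 subsections/letter, 1000 sentences/subsection — exceeding either is
an error, not silent truncation).

Character offsets are 0-based and end-exclusive everywhere, chosen so an
annotation's entity text is always exactly `sentence[start:end]`; this is
asserted corpus-wide. The sentence splitter is a pluggable contract
(`text -> [(start, end)]`); the shipped default is rule-based and avoids
splitting at decimal points, "e.g."/"i.e.", figure references and
single-letter initials. Any splitter satisfying the contract may replace
it, since gold fixtures carry their own boundaries.

## Dictionary and rule-based annotation

The dictionary is a flat set of names and synonyms with curation statuses
(`quantified`, `detected`, `expected`, `predicted`); by default only
quantified/detected entries load, because expected/predicted entries
inflate the dictionary roughly fourfold for little precision. Cleaning
removes entries of length ≤ 5 unless whitelisted (shipped whitelist:
ATP-like strings that are metabolite-exclusive in practice) and a
blocklist of common-word synonyms ("result" is a synonym of omeprazole).
Both lists are plain text and user-replaceable; the shipped versions are
starters, not curated authorities.

Matching is case-insensitive at word boundaries, where letters, digits
*and hyphens* count as word-internal — so "glucose" matches in
"(glucose)" but not inside "glucoses" or "D-glucose". Overlapping
dictionary candidates resolve longest-match-first.

Regular expressions complement the dictionary for morphology-regular
names. A *reference set* (entries containing a space, hyphen or colon)
supports the recursive crafting workflow: `pattern_coverage` reports the
fraction of reference terms with at least a partial match and lists the
uncovered ones. The shipped pattern set targets common metabolite
morphology (suffixes -ate/-ose/-ine, "-ic acid", substituent prefixes,
lipid shorthand like `PC(16:0/18:1)`); it is a starting point stored in a
plain text file, one expression per line, and fully user-replaceable.
Partial matches are expanded to the whitespace-delimited word(s) they
touch, shedding trailing sentence punctuation.

Post-processing runs three fixups to a fixpoint (capped at 20 iterations;
hitting the cap is an error):

1. **Adjacent-word extension.** The preceding word is prepended iff it
   ends with a hyphen or digit, the entity starts with ","+digit, or the
   entity's first word starts with a hyphen — never when the preceding
   word is a stopword. The following word is appended under the mirrored
   rules, plus when it is one of "acid", "isomer", "ester", "ether". The
   mirroring of the digit rule to the append case (entity ends with a
   digit) is an interpretation; the source convention is ambiguous and the
   choice is documented here and pinned by tests.
2. **Bracket balancing.** For each of `()[]{}`, an entity missing one side
   gains the missing bracket. The span is only grown when the missing
   bracket is the adjacent sentence character; otherwise the fix would
   break the entity-equals-substring invariant, so it is left unapplied
   (`balance_brackets` on bare text performs the textual fix for callers
   that want it).
3. **Merging.** Entities that overlap, touch, or are separated only by
   whitespace merge transitively.

Within one iteration the order is extend → balance → merge; the fixpoint
requirement makes most orderings equivalent, and this one is the
documented default. Coordinated mentions ("1- and 3-methylhistidine")
deliberately yield only the surface form present in the dictionary;
recovering the elided variant needs semantic analysis and is out of scope.

## Name-internal features (pre-classifier)

A random forest is trained from the dictionary alone: entries are
tokenised and labelled B/I/E/S by position, a negative lexicon of common
words is labelled O (the O class is included — probability contrast
against non-names is what makes the features useful). Features are
CRC32-hashed character 1–3-grams (64 signed buckets, L2-normalised) plus
shape features (length, digit/hyphen/bracket/colon presence, case
pattern, vowel fraction). Nothing about the sentence context enters, so
the scores degrade gracefully on misspelled or unseen names — which is
precisely what the sequence model exploits. The classifier family is
replaceable behind `score_tokens`; rows always sum to 1 over the fixed
class order (O, B, I, E, S).

## Sequence tagger

Per token, the network consumes the 5-dim name-internal probability row
and a word embedding. The name-internal side passes through a width-3
convolution with 256 filters (ReLU, same padding); the concatenation with
the embedding — 256+300 = 556 wide for context-free embeddings, 256+768 =
1024 for contextual — feeds a bidirectional LSTM and a per-token dense
softmax over the five BIOES classes. For contextual embeddings a channel
(spatial) dropout of 0.25 is applied to the embedding during training.
Embedders are frozen and pluggable: a text word-vector file for the
context-free kind; any transformer's last hidden layer satisfies the
contextual contract (the shipped `HashedContextualEmbedder` is a
deterministic synthetic stand-in for exercising that code path, not a
language model).

The network and its backpropagation are implemented directly in numpy
(verified against finite differences); no deep-learning framework is
required. Unstated training details are package defaults, all in
`ModelConfig`: Adam with learning rate 1e-3, batch size 32, 50 epochs,
recurrent width 300 (reduced in desk-scale tests), no class weighting,
and **word-level embedding dropout 0.1** — whole token vectors are zeroed
at random during training so the tagger learns to fall back on
name-internal features and context for out-of-vocabulary tokens. That
last choice matters: without it, a model trained where every entity token
has an in-vocabulary embedding over-relies on the lookup and misses
misspelled names at prediction time.

After every epoch, span-level F1 is computed on the validation set and
the best epoch's weights are kept. Decoding is argmax over classes
followed by explicit repair of illegal BIOES sequences — the default
"conservative" policy drops orphan I/E labels and unclosed B-blocks; a
"permissive" policy instead turns every maximal non-O run into a span.
Decoded spans then pass through the same extend/balance/merge fixups as
the rule pipeline. Sentences longer than `max_tokens` are processed in
overlapping windows, each token keeping the prediction from the window
where it sits furthest from an edge.

## Document application

Either annotator applies to whole articles: the filtered A/M/R/D
sentences, each table cell as a standalone sentence (with a synthetic
`T<table><row><col>` identifier outside the A/M/R/D ID space, never
written to corpus files), and abbreviations. A short form is linked iff
its *entire* definition is recognised as a single entity with no
incomplete-entity fixups applied; all whole-word, case-sensitive
occurrences of the short form then become abbreviation-sourced records.
The three sources partition the record set and are evaluated separately.

## Evaluation

Matching is exact on (article, sentence, start, end) — no partial credit
by default (an overlap mode exists but is never used for headline
numbers). Scores: precision, recall, F1 = 2pr/(p+r), and
F* = pr/(p+r−pr), which is ≤ F1 everywhere with equality only at
p = r = 1. Reports round to 4 decimal places, half-even. Per-section
scores partition records by the sentence's section group (A/M/R/RD/D) and
their tp/fp/fn sums are asserted to reproduce the global counts. Corpus
summaries count each case-folded entity once per article; group means are
reported to 1 decimal place.

## Co-occurrence networks

Node weight = number of articles reporting the metabolite; edge weight =
number of articles reporting both endpoints (once per article, however
often the pair co-occurs inside it). Entity identity is the case-folded
surface string — no synonym resolution, so "glucose" and "D-glucose" are
distinct nodes. By default only abstract, results (including tables) and
discussion sections feed the graph. The `top_article` node attribute
(most-mentioning article, ties to the lower article ID) supports
colouring; layout is left to external tools via the weighted adjacency
TSV and GEXF exports.

## Synthetic fixtures

The generator emulates the *structure* of the corpus: A/M/R/D (or
combined RD) sections with subsections, template sentences with planted
dictionary names and plant-time gold spans, tables with metabolite cells,
defined abbreviations, and single-character typo corruptions flagged
separately from exact mentions. The template scaffold vocabulary is
deliberately disjoint from everything the shipped pattern set matches, so
at typo rate 0 the rule pipeline must recover exactly the planted spans —
a green test there establishes the matching and fixup machinery, not
performance on real prose. The generator does not emulate linguistic
variety, encoding artefacts, or ambiguous synonyms; corpus-scale scores
on real articles require the real corpus and dictionary and are out of
scope for the test suite.

Defaults state the emulated world: typo rate 0 (corruptions are opt-in),
abbreviation rate 0.3, table rate 0.7, combined-RD rate 0.25, 2–4
sentences per subsection. All outputs are byte-determined by the seed.

## Known limitations

- The stdlib `re` engine cannot be interrupted mid-search, so the
  per-pattern timeout guard only triggers between matches; a genuinely
  catastrophic pattern can still stall a single search call.
- The chem-word tokenizer is a contract plus rules, not a re-implementation
  of any specific chemistry tokenizer; token-boundary quirks differ.
- Bracket fixes that cannot be realised by span growth are dropped rather
  than recorded as virtual entities.
- The numpy tagger is CPU-scale: suitable for the synthetic corpus and
  small real workloads, not for training on tens of thousands of
  sentences.
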