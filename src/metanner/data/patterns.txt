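# Default metabolite regular-expression pattern set, v1.
# One expression per line; '#' starts a comment. Patterns provide PARTIAL
# matches that the annotator expands to whole words. The set is crafted
# against common metabolite morphology and is fully user-replaceable; use
# dictionary.pattern_coverage to measure and iteratively extend it against
# a reference set.
#
# anionic/ester suffixes (lactate, citrate, pyruvate, ...)
\b[a-z]{4,}(?:ate|ates)\b
# sugars and related (-ose), incl. phosphorylated forms
\b[a-z]{3,}ose\b
# amines / amino acids / nucleosides (-ine, -osine)
\b[a-z]{4,}ine\b
# alcohols and sterols (-ol, -itol, -erol)
\b[a-z]{4,}(?:itol|erol|anol|sterol)\b
# "-ic acid" names (citric acid, palmitic acid, ...)
\b[a-z]{3,}(?:ic|oic|aric|onic|uric)\s+acids?\b
# substituent prefixes, optionally with locants (4-hydroxy-, N-acetyl-, ...)
\b(?:\d+(?:,\d+)*-|[NO]-)?(?:hydroxy|methyl|dimethyl|acetyl|phospho|amino|keto|oxo|desmethyl|glycero|sphingo)
# lipid shorthand: PC(16:0/18:1), SM(d18:1/16:0), LPC(18:2), ...
\b[A-Z]{2,5}\((?:[a-z]?\d+:\d+)(?:/[a-z]?\d+:\d+)*\)
# acyl chain ratios standing alone, e.g. 18:2n-6
\b\d{1,2}:\d(?:n-\d)?\b
# conjugates and carnitines
\b[a-z]{3,}(?:carnitine|choline|inositol|cholate|glucuronide)\b
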