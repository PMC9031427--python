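# Short (<=5 characters) strings kept in dictionaries despite their length,
# because they are metabolite-exclusive in practice. User-replaceable.
ATP
ADP
AMP
GTP
GDP
NAD
NADH
NADP
TMAO
urea
FAD
cAMP
cGMP
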