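# Common-word metabolite synonyms removed from dictionaries by default.
# One term per line, matched case-insensitively. Fully user-replaceable.
result
results
retinal
lead
iron
gold
silver
target
factor
base
acid rain
process
success
urea cycle
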