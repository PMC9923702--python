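# Overrides for the 499-cell kinetic-tree benchmark: a wider adaptive
# neighbourhood range and a log transform for the count-scale expression.
kmax = 200
log1p = true
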