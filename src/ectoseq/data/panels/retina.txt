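# Neural retina marker genes
RHO
SAG
RCVRN
NRL
PVALB
PDE6G
GNAT1
GNGT1
RBP3
PRPH2
VSX2
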