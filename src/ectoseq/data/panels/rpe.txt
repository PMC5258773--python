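# Retinal pigment epithelium marker genes
RPE65
MITF
TYR
PMEL
TYRP1
BEST1
OCA2
CHRNA3
SERPINF1
RDH5
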