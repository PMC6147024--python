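# DNA methylation machinery regulator panel
DNMT1
DNMT3A
DNMT3B
UHRF1
UHRF2
TET1
TET2
TET3
APOBEC3F
APOBEC3G
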