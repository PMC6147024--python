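# Viral-mimicry / immune gene panel (30 genes): type-I-IFN-stimulated and
# dsRNA-sensing genes whose de-repression accompanies genomic hypomethylation.
IFI44
IFI27
OASL
IL29
IFNB1
IRF7
DDX58
IRF1
TLR3
IFI6
IFI16
IFI35
IFIT1
IFIT2
IFIT3
IFITM1
ISG15
ISG20
MX1
MX2
OAS1
OAS2
OAS3
IRF9
STAT1
STAT2
CXCL10
DDX60
IFIH1
IL15
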