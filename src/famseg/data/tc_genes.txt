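# Starter list of genes previously associated with familial papillary or
# medullary thyroid cancer (one HGNC symbol per line, matched
# case-insensitively). Users with a fuller curated set (e.g. a DisGeNET
# thyroid-carcinoma export) can pass their own file instead.
RET
MSH6
FOXM1
EPCAM
HOOK3
BMP1
TG
NTRK1
DICER1
SRGAP1
SRRM2
MYO1F
MAP2K5
NOP53
FOXE1
MYH9
NKX2-1
DIRC3
CHEK2
TINF2
POT1
PTCSC2
APC
PTEN
WRN
PRKAR1A
SDHB
SDHD
MEN1
CDKN1B
TP53
BRAF
NRAS
HRAS
KRAS
TERT
TSHR
PAX8
PPARG
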