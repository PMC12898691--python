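# Positive-control gene set: human Krebs (TCA) cycle enzymes,
# KEGG pathway hsa00020 membership (HGNC symbols).
ACLY
ACO1
ACO2
CS
DLAT
DLD
DLST
FH
IDH1
IDH2
IDH3A
IDH3B
IDH3G
MDH1
MDH2
OGDH
OGDHL
PC
PCK1
PCK2
PDHA1
PDHA2
PDHB
SDHA
SDHB
SDHC
SDHD
SUCLA2
SUCLG1
SUCLG2
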