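# Default Alzheimer's-disease risk-gene list (52 symbols, one per line).
# Assembled from replicated AD GWAS loci reported in the literature; intended
# as a convenience default -- supply your own list for real analyses.
ABCA7
SORCS1
SORL1
PILRA
PFDN1
PLXNA4
TRIP4
CD2AP
CD33
PLCG2
APOE
ECHDC3
CLU
CR1
BIN1
PICALM
MS4A4A
MS4A6A
EPHA1
INPP5D
MEF2C
PTK2B
NME8
ZCWPW1
CELF1
FERMT2
SLC24A4
CASS4
DSG2
ABI3
SPI1
APH1B
ADAM10
KAT8
ACE
ADAMTS1
HESX1
CNTNAP2
HS3ST1
CLNK
SCIMP
TREM2
APP
PSEN1
PSEN2
HLA-DRB1
IQCK
WWOX
ADAM17
TNIP1
GRN
SHARPIN
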