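# Curated tag list of canonical breast-cancer driver genes, used to flag
# driver-gene hits in burden summaries.
gene
AKT1
AKT2
ARID1A
ARID1B
ARID2
ASXL1
ASXL2
ATM
ATR
BAP1
BRAF
BRCA1
BRCA2
BRIP1
CASP8
CBFB
CCND1
CCND3
CDH1
CDKN1A
CDKN1B
CDKN2A
CHEK2
CREBBP
CTCF
CTNNB1
DNMT3A
EGFR
EP300
ERBB2
ERBB3
ERBB4
ESR1
FANCA
FANCD2
FBXW7
FGFR1
FGFR2
FOXA1
FOXO3
FOXP1
GATA3
GPS2
HRAS
JAK1
KDM6A
KMT2C
KMT2D
KRAS
MAP2K4
MAP3K1
MAP3K13
MDM2
MDM4
MEN1
MLH1
MSH2
MSH6
MYC
NCOR1
NF1
NF2
NOTCH1
NOTCH2
NRAS
PALB2
PBRM1
PDGFRA
PIK3CA
PIK3R1
PMS2
PTEN
PTPN22
PTPRD
RB1
RUNX1
SETD2
SF3B1
SMAD2
SMAD4
SMARCA4
SMARCB1
SMARCD1
SPEN
STAG2
STK11
TBX3
TP53
USP9X
XBP1
ZFP36L1
ZFP36L2
ZMYM3
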