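# Compact gene model (hg19 coordinates, 1-based closed) for gene-level
# copy-number calls: canonical breast-cancer genes with approximate loci.
gene	chrom	start	end
MDM4	chr1	204485511	204542871
AKT3	chr1	243651535	244006886
ARID1A	chr1	27022522	27108601
MYCL	chr1	40361096	40367687
PIK3CA	chr3	178866311	178952497
CTNNB1	chr3	41240942	41281939
FGFR3	chr4	1795039	1810599
TERT	chr5	1253287	1295162
APC	chr5	112043202	112181936
ESR1	chr6	152011631	152424408
EGFR	chr7	55086725	55275031
KMT2C	chr7	151832010	152133090
BRAF	chr7	140419127	140624564
FGFR1	chr8	38268656	38326352
ZNF703	chr8	37553329	37557466
MYC	chr8	128748315	128753680
IL7	chr8	79587978	79717758
HEY1	chr8	80676244	80680098
CDKN2A	chr9	21967751	21995300
GATA3	chr10	8096667	8117164
PTEN	chr10	89623195	89728532
FGFR2	chr10	123237848	123357972
CCND1	chr11	69455873	69469242
ATM	chr11	108093211	108239829
KRAS	chr12	25358180	25403854
MDM2	chr12	69201956	69239214
BRCA2	chr13	32889611	32973805
RB1	chr13	48877887	49056122
AKT1	chr14	105235686	105262080
IGF1R	chr15	99192200	99507759
CDH1	chr16	68771128	68869444
TP53	chr17	7571720	7590868
MAP2K4	chr17	11924135	12047147
NF1	chr17	29421945	29704695
ERBB2	chr17	37844167	37886679
BRCA1	chr17	41196312	41277500
SMAD4	chr18	48556583	48611411
STK11	chr19	1205798	1228434
CCNE1	chr19	30302805	30315215
AURKA	chr20	54944445	54967393
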