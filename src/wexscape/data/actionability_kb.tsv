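# Frozen mini knowledge base of actionable genomic alterations.
# variant_filter: '|'-separated protein-change hotspots, or '.' for any
# qualifying alteration of the gene.  oncokb_loe in {1,2,3,4,none};
# escat in {I,II,none}.
gene	alteration_type	variant_filter	oncokb_loe	escat
ERBB2	amplification	.	1	I
PIK3CA	mutation	E542K|E545K|E545A|E545G|Q546E|Q546R|H1047R|H1047L|H1047Y	1	I
BRCA1	mutation	.	1	I
BRCA1	deletion	.	1	I
BRCA2	mutation	.	1	I
BRCA2	deletion	.	1	I
PTEN	deletion	.	3	II
AKT1	mutation	E17K	3	II
ESR1	mutation	D538G|Y537S|Y537N|Y537C|E380Q	3	II
ERBB2	mutation	L755S|V777L|S310F	3	II
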