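center	layer	all_subjects	ctrl_lc	ctrl_hcc	lc_hcc	printed_signature	printed_severity	ctrl_mean	lc_mean	hcc_mean
Ruminococcus gnavus group	bacteria	1	0	1	0	HCC specific	-
Succinatimonas	bacteria	1	1	0	0	LC specific	-
Enterobacter	bacteria	0	1	0	0	LC specific	-
Oxalobacter	bacteria	0	0	1	0	HCC specific	-
Ruminococcaceae UCG 002	bacteria	0	0	0	1	-	Yes
Ruminococcaceae UCG 005	bacteria	0	0	0	1	-	Yes
Negativibacillus	bacteria	0	0	0	1	-	Yes
Tyzzerella 3	bacteria	0	0	0	1	-	Yes
Stenotrophomonas virus DLP5	virus	1	1	1	0	Common	-
Uncultured Caudovirales phage	virus	1	1	1	1	Common	Yes
Escherichia virus ECBP5	virus	0	1	0	0	LC specific	-
Uncultured Mediterranean phage uvMED	virus	0	1	0	0	LC specific	-
Actinomyces virus Av1	virus	0	0	0	1	-	Yes
Azobacteroides phage ProJPt-Bp1	virus	0	0	0	1	-	Yes
Bacteroides phage B124-14	virus	0	0	0	1	-	Yes
Bacteroides phage B40-8	virus	0	0	0	1	-	Yes
Clostridium phage phiCTP1	virus	0	0	0	1	-	Yes
Flavobacterium phage Fpv3	virus	0	0	0	1	-	Yes
Pectobacterium phage DU_PP_III	virus	0	0	0	1	-	Yes
Streptococcus phage Dp-1	virus	0	0	0	1	-	Yes
Threonine	metabolite	1	0	1	1	HCC specific	Yes
Pyruvic acid	metabolite	1	1	1	0	Common	-
Leucine	metabolite	1	0	1	0	HCC specific	-
Acetic acid	metabolite	1	0	0	0	Common *	-	39.1	150.8	200.5
Methionine	metabolite	0	0	1	0	HCC specific	-
Formic acid	metabolite	0	0	0	1	-	Yes
3-Hydroxybutyric acid	metabolite	0	0	0	1	-	Yes
Succinic acid	metabolite	0	0	0	1	-	Yes
Eotaxin	cytokine	1	1	1	0	Common	-
IL-1b	cytokine	1	1	0	0	LC specific	-
MCP-1	cytokine	1	1	0	1	LC specific	Yes
PDGF-AB/BB	cytokine	1	0	0	0	Common *	-	17.9	75.9	51.6
IL-10	cytokine	0	1	0	1	LC specific	Yes
FGF-2	cytokine	0	1	0	0	LC specific	-
IL-17A	cytokine	0	0	1	0	HCC specific	-
MIP-1b	cytokine	0	0	1	0	HCC specific	-
IL-8	cytokine	0	0	1	0	HCC specific	-
GM-CSF	cytokine	0	0	0	1	-	Yes
RANTES	cytokine	0	0	0	1	-	Yes
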