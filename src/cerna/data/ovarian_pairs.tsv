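# Published significant Spearman pairs from the ovarian-cancer validation
# cohort (46 matched tumor/normal pairs). All pairs had adjusted p < 0.05;
# the source table prints rho only, so p/q are left unset.
id_a	class_a	id_b	class_b	rho	pair_type
miR-148a	miRNA	MAFG-DT	lncRNA	-0.37	miRNA-lncRNA
miR-203a	miRNA	MALAT1	lncRNA	-0.42	miRNA-lncRNA
miR-203a	miRNA	OIP5-AS1	lncRNA	-0.42	miRNA-lncRNA
miR-203a	miRNA	MLK7-AS1	lncRNA	-0.41	miRNA-lncRNA
miR-203a	miRNA	LINC00339	lncRNA	-0.39	miRNA-lncRNA
miR-148a	miRNA	BCL2	mRNA	-0.44	miRNA-mRNA
miR-203a	miRNA	CDK4	mRNA	-0.54	miRNA-mRNA
miR-203a	miRNA	c-MET	mRNA	-0.42	miRNA-mRNA
miR-203a	miRNA	ZEB1	mRNA	-0.34	miRNA-mRNA
miR-203a	miRNA	ZEB2	mRNA	-0.41	miRNA-mRNA
miR-203a	miRNA	WNT4	mRNA	-0.41	miRNA-mRNA
miR-203a	miRNA	YAP1	mRNA	-0.53	miRNA-mRNA
MAFG-DT	lncRNA	BCL2	mRNA	0.45	lncRNA-mRNA
MALAT1	lncRNA	CDK4	mRNA	0.52	lncRNA-mRNA
MALAT1	lncRNA	c-MET	mRNA	0.39	lncRNA-mRNA
MALAT1	lncRNA	ZEB1	mRNA	0.38	lncRNA-mRNA
OIP5-AS1	lncRNA	CDK4	mRNA	0.53	lncRNA-mRNA
OIP5-AS1	lncRNA	c-MET	mRNA	0.37	lncRNA-mRNA
OIP5-AS1	lncRNA	WNT4	mRNA	0.56	lncRNA-mRNA
OIP5-AS1	lncRNA	YAP1	mRNA	0.61	lncRNA-mRNA
OIP5-AS1	lncRNA	ZEB1	mRNA	0.57	lncRNA-mRNA
OIP5-AS1	lncRNA	ZEB2	mRNA	0.65	lncRNA-mRNA
MLK7-AS1	lncRNA	CDK4	mRNA	0.40	lncRNA-mRNA
MLK7-AS1	lncRNA	YAP1	mRNA	0.51	lncRNA-mRNA
MLK7-AS1	lncRNA	ZEB2	mRNA	0.49	lncRNA-mRNA
LINC00339	lncRNA	CDK4	mRNA	0.53	lncRNA-mRNA
LINC00339	lncRNA	YAP1	mRNA	0.55	lncRNA-mRNA
LINC00339	lncRNA	ZEB1	mRNA	0.43	lncRNA-mRNA
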