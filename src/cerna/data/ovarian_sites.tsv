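# Published miR-203a binding-site annotations for the correlated lncRNAs
# and mRNAs (TargetScan v7.2 / DIANA-TarBase v8 site-type calls). The
# source gives hg19 genomic windows, not transcript coordinates, so
# start/end are unset here; only the site-type call is used downstream.
mirna_id	transcript_id	start	end	site_type
miR-203a	MALAT1			no binding site
miR-203a	OIP5-AS1			7mer-m8
miR-203a	MLK7-AS1			7mer-m8
miR-203a	LINC00339			no binding site
miR-203a	CDK4			no binding site
miR-203a	c-MET			8mer
miR-203a	WNT4			no binding site
miR-203a	YAP1			no binding site
miR-203a	ZEB1			7mer-m8
miR-203a	ZEB2			8mer
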