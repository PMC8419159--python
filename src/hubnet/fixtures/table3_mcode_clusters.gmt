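mcode_cluster_1	densely interrelated region 1 of the angiogenesis/inflammation/matrix PPI network	HBEGF	MMP9	SERPINB2	ADAMTS1	NR4A2	MMP10	IL1B	CCL2	NR4A1	AKT1	MTOR	MAPK1	CXCL1	VEGFC	CLDN1
mcode_cluster_2	densely interrelated region 2	MMP2	MMP1	MMP14	PTGS2	ACKR3	TNFAIP6	PLAU	CDKN1A	TIMP2	IL-6
mcode_cluster_3	densely interrelated region 3	ADAMTS5	PIK3R3	C3AR1	C5AR1	C2	CTNNB1	C3	FOXO1	CXCL8	ANGPT2	CFI
mcode_cluster_4	densely interrelated region 4	PIK3R1	BCL2L1	STAT3	BAD	CCND1	PIK3CA	CFB	C5
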