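# Curated seed genes: angiogenesis-, inflammation- and matrix-related proteins
# selected by repetition frequency across text mining, microarray and PPI studies.
# One gene symbol per line, as printed (official-symbol dialect not enforced).
MMP2
MMP9
MMP10
MMP14
C3
C5
CFB
CFI
CCL2
BCL2L1
IL-6
CCND1
RCAN1
ANGPT2
TNFAIP6
FOXO1
CTNNB1
CXCL1
ADAMTS5
PIK3R1
PLCB3
CDKN1B
mTOR
AKT1
PTGS2
NR4A1
PIK3CA
PLAU
VEGFC
ACKR3
ADAMTS1
STAT3
ARHGAP22
MAPK1
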