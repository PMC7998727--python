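gene	role	reference
CDKN2A	G1	GSEA
CDKN2B	G1	GSEA
CCND1	G1	GSEA
DHFR	G1/S	GSEA
CCNE1	G1/S	GSEA
AKT1	S	GSEA
AKT2	S	GSEA
AKT3	S	GSEA
E2F4	S	GSEA
E2F5	S	GSEA
CDKN2D	G2	GSEA
MDM2	G2	GSEA
CCNB2	G2/M	GSEA
TOPBP1	G2/M	GSEA
APC	M	GSEA
BUB1	M	GSEA
E2F2	M/G1	GSEA
E2F3	M/G1	GSEA
CCNB1	M/G1	GSEA
MYBL2	up_in_cancer	Li et al.
FOXM1	up_in_cancer	Li et al.
AURKA	up_in_cancer	Li et al.
AURKB	up_in_cancer	Li et al.
SCARA5	down_in_cancer	Li et al.
MYOM1	down_in_cancer	Li et al.
PCNA	proliferative_marker	Whitfield et al.
MKI67	proliferative_marker	Whitfield et al.
MCM2	proliferative_marker	Whitfield et al.
MCM3	proliferative_marker	Whitfield et al.
MCM4	proliferative_marker	Whitfield et al.
MCM5	proliferative_marker	Whitfield et al.
MCM6	proliferative_marker	Whitfield et al.
E2F1	proliferative_marker	Whitfield et al.
RNASEH2A	rnaseh	this study
RNASEH2B	rnaseh	this study
RNASEH2C	rnaseh	this study
RNASEH1	rnaseh	this study
CCT8	predicted_partner	this study
DNAJA1	predicted_partner	this study
AIFM1	predicted_partner	this study
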