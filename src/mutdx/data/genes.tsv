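# term	canonical	kind
PON1	PON1	gene
BRCA1	BRCA1	gene
BRCA2	BRCA2	gene
SELP	SELP	gene
PSGL-1	PSGL-1	gene
PSGL1	PSGL-1	gene
ELAC2/HPC2	ELAC2/HPC2	gene
ELAC2	ELAC2/HPC2	gene
HPC2	ELAC2/HPC2	gene
XRCC1	XRCC1	gene
NDPK-A	NDPK-A	gene
NME1	NDPK-A	gene
HFE	HFE	gene
RRM1	RRM1	gene
KLF6	KLF6	gene
CMKLR1	CMKLR1	gene
chemokine-like receptor 1	CMKLR1	gene
ABCC11	ABCC11	gene
MLH1	MLH1	gene
hMLH1	MLH1	gene
AR	AR	gene
Androgen Receptor	AR	gene
CTLA-4	CTLA-4	gene
CTLA4	CTLA-4	gene
stromelysin-1	MMP3	gene
matrix metalloproteinase-3	MMP3	gene
MMP3	MMP3	gene
interleukin-6	IL6	gene
IL-6	IL6	gene
IL6	IL6	gene
TP53	TP53	gene
EGFR	EGFR	gene
KRAS	KRAS	gene
NRAS	NRAS	gene
HRAS	HRAS	gene
BRAF	BRAF	gene
PIK3CA	PIK3CA	gene
PTEN	PTEN	gene
APC	APC	gene
SMAD4	SMAD4	gene
CDKN2A	CDKN2A	gene
RB1	RB1	gene
MYC	MYC	gene
ERBB2	ERBB2	gene
MET	MET	gene
ALK	ALK	gene
ROS1	ROS1	gene
RET	RET	gene
KIT	KIT	gene
PDGFRA	PDGFRA	gene
FLT3	FLT3	gene
JAK2	JAK2	gene
ABL1	ABL1	gene
NPM1	NPM1	gene
DNMT3A	DNMT3A	gene
IDH1	IDH1	gene
IDH2	IDH2	gene
TET2	TET2	gene
ASXL1	ASXL1	gene
EZH2	EZH2	gene
NOTCH1	NOTCH1	gene
FBXW7	FBXW7	gene
CTNNB1	CTNNB1	gene
AXIN1	AXIN1	gene
VHL	VHL	gene
MTOR	MTOR	gene
TSC1	TSC1	gene
TSC2	TSC2	gene
NF1	NF1	gene
NF2	NF2	gene
ATM	ATM	gene
ATR	ATR	gene
CHEK2	CHEK2	gene
PALB2	PALB2	gene
RAD51	RAD51	gene
RAD50	RAD50	gene
NBN	NBN	gene
MRE11	MRE11	gene
MSH2	MSH2	gene
MSH6	MSH6	gene
PMS2	PMS2	gene
EPCAM	EPCAM	gene
MUTYH	MUTYH	gene
CDH1	CDH1	gene
STK11	STK11	gene
TGFBR2	TGFBR2	gene
ESR1	ESR1	gene
PGR	PGR	gene
AKT1	AKT1	gene
AKT2	AKT2	gene
GATA3	GATA3	gene
MAP2K1	MAP2K1	gene
MAP2K2	MAP2K2	gene
MAP3K1	MAP3K1	gene
FGFR1	FGFR1	gene
FGFR2	FGFR2	gene
FGFR3	FGFR3	gene
FGFR4	FGFR4	gene
CCND1	CCND1	gene
CDK4	CDK4	gene
CDK6	CDK6	gene
MDM2	MDM2	gene
MDM4	MDM4	gene
ARID1A	ARID1A	gene
ARID1B	ARID1B	gene
SMARCA4	SMARCA4	gene
SMARCB1	SMARCB1	gene
BAP1	BAP1	gene
SETD2	SETD2	gene
PBRM1	PBRM1	gene
KDM5C	KDM5C	gene
KDM6A	KDM6A	gene
CREBBP	CREBBP	gene
EP300	EP300	gene
SF3B1	SF3B1	gene
SRSF2	SRSF2	gene
U2AF1	U2AF1	gene
ZRSR2	ZRSR2	gene
RUNX1	RUNX1	gene
CEBPA	CEBPA	gene
GATA2	GATA2	gene
WT1	WT1	gene
PHF6	PHF6	gene
BCOR	BCOR	gene
STAG2	STAG2	gene
RAD21	RAD21	gene
SMC1A	SMC1A	gene
SMC3	SMC3	gene
TERT	TERT	gene
ATRX	ATRX	gene
DAXX	DAXX	gene
MEN1	MEN1	gene
GNAS	GNAS	gene
GNAQ	GNAQ	gene
GNA11	GNA11	gene
SDHA	SDHA	gene
SDHB	SDHB	gene
SDHC	SDHC	gene
SDHD	SDHD	gene
FH	FH	gene
PTCH1	PTCH1	gene
SMO	SMO	gene
GLI1	GLI1	gene
SUFU	SUFU	gene
DICER1	DICER1	gene
PRKAR1A	PRKAR1A	gene
POLE	POLE	gene
POLD1	POLD1	gene
AXIN2	AXIN2	gene
BMPR1A	BMPR1A	gene
GREM1	GREM1	gene
CDC73	CDC73	gene
CASR	CASR	gene
RET2	RET2	gene
MAX	MAX	gene
TMEM127	TMEM127	gene
KIF1B	KIF1B	gene
EGLN1	EGLN1	gene
CUL3	CUL3	gene
NFE2L2	NFE2L2	gene
KEAP1	KEAP1	gene
RIT1	RIT1	gene
SOS1	SOS1	gene
PTPN11	PTPN11	gene
RAF1	RAF1	gene
SHOC2	SHOC2	gene
CBL	CBL	gene
NSD1	NSD1	gene
EZH1	EZH1	gene
SUZ12	SUZ12	gene
EED	EED	gene
SETBP1	SETBP1	gene
SRC	SRC	gene
YES1	YES1	gene
FYN	FYN	gene
LCK	LCK	gene
HCK	HCK	gene
FGR	FGR	gene
BLK	BLK	gene
LYN	LYN	gene
FRK	FRK	gene
CSK	CSK	gene
CYP1A1	CYP1A1	gene
CYP2D6	CYP2D6	gene
CYP2C19	CYP2C19	gene
CYP2C9	CYP2C9	gene
CYP3A4	CYP3A4	gene
CYP19A1	CYP19A1	gene
GSTM1	GSTM1	gene
GSTT1	GSTT1	gene
GSTP1	GSTP1	gene
NAT1	NAT1	gene
NAT2	NAT2	gene
SULT1A1	SULT1A1	gene
UGT1A1	UGT1A1	gene
TPMT	TPMT	gene
DPYD	DPYD	gene
MTHFR	MTHFR	gene
MTR	MTR	gene
MTRR	MTRR	gene
TYMS	TYMS	gene
DHFR	DHFR	gene
SLC19A1	SLC19A1	gene
ABCB1	ABCB1	gene
ABCC1	ABCC1	gene
ABCC2	ABCC2	gene
ABCG2	ABCG2	gene
SLCO1B1	SLCO1B1	gene
VDR	VDR	gene
ESR2	ESR2	gene
SHBG	SHBG	gene
CYP17A1	CYP17A1	gene
SRD5A2	SRD5A2	gene
HSD17B1	HSD17B1	gene
INSR	INSR	gene
IGF1	IGF1	gene
IGF1R	IGF1R	gene
IGF2	IGF2	gene
IGFBP3	IGFBP3	gene
TNF	TNF	gene
LTA	LTA	gene
IL1A	IL1A	gene
IL1B	IL1B	gene
IL2	IL2	gene
IL4	IL4	gene
IL8	IL8	gene
IL10	IL10	gene
IL12A	IL12A	gene
IL13	IL13	gene
IL18	IL18	gene
IFNG	IFNG	gene
TGFB1	TGFB1	gene
VEGFA	VEGFA	gene
KDR	KDR	gene
HIF1A	HIF1A	gene
EPAS1	EPAS1	gene
NOS2	NOS2	gene
NOS3	NOS3	gene
PTGS2	PTGS2	gene
ALOX5	ALOX5	gene
LEP	LEP	gene
LEPR	LEPR	gene
ADIPOQ	ADIPOQ	gene
PPARG	PPARG	gene
PPARGC1A	PPARGC1A	gene
APOE	APOE	gene
LPL	LPL	gene
CETP	CETP	gene
PCSK9	PCSK9	gene
LDLR	LDLR	gene
XRCC2	XRCC2	gene
XRCC3	XRCC3	gene
XRCC4	XRCC4	gene
ERCC1	ERCC1	gene
ERCC2	ERCC2	gene
ERCC4	ERCC4	gene
ERCC5	ERCC5	gene
XPA	XPA	gene
XPC	XPC	gene
OGG1	OGG1	gene
APEX1	APEX1	gene
LIG4	LIG4	gene
PRKDC	PRKDC	gene
TP73	TP73	gene
CASP8	CASP8	gene
CASP10	CASP10	gene
FAS	FAS	gene
FASLG	FASLG	gene
BCL2	BCL2	gene
BAX	BAX	gene
BIRC5	BIRC5	gene
RNASEL	RNASEL	gene
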