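# Reconstructed default gene panel (168 hereditary-cancer genes).
# The published gene list is not reproduced in the main text; this
# reconstruction is a stand-in and is fully user-replaceable.
symbol	pathway	inheritance	acmg_return	actionable_class
BAP1	HR	DOMINANT	false	NONE
BARD1	HR	DOMINANT	false	NONE
BLM	HR	DOMINANT	false	NONE
BRCA1	HR	DOMINANT	true	PARPI
BRCA2	HR	DOMINANT	true	PARPI
BRIP1	HR	DOMINANT	false	NONE
DMC1	HR	DOMINANT	false	NONE
EME1	HR	DOMINANT	false	NONE
GEN1	HR	DOMINANT	false	NONE
MRE11	HR	DOMINANT	false	NONE
MUS81	HR	DOMINANT	false	NONE
NBN	HR	DOMINANT	false	NONE
PALB2	HR	DOMINANT	false	NONE
POLQ	HR	DOMINANT	false	NONE
RAD50	HR	DOMINANT	false	NONE
RAD51	HR	DOMINANT	false	NONE
RAD51B	HR	DOMINANT	false	NONE
RAD51C	HR	DOMINANT	false	NONE
RAD51D	HR	DOMINANT	false	NONE
RAD52	HR	DOMINANT	false	NONE
RAD54B	HR	DOMINANT	false	NONE
RAD54L	HR	DOMINANT	false	NONE
RECQL	HR	DOMINANT	false	NONE
RECQL4	HR	DOMINANT	false	NONE
RECQL5	HR	DOMINANT	false	NONE
WRN	HR	DOMINANT	false	NONE
XRCC2	HR	DOMINANT	false	NONE
XRCC3	HR	DOMINANT	false	NONE
FAN1	FANCONI	DOMINANT	false	NONE
FANCA	FANCONI	DOMINANT	false	NONE
FANCB	FANCONI	DOMINANT	false	NONE
FANCC	FANCONI	DOMINANT	false	NONE
FANCD2	FANCONI	DOMINANT	false	NONE
FANCE	FANCONI	DOMINANT	false	NONE
FANCF	FANCONI	DOMINANT	false	NONE
FANCG	FANCONI	DOMINANT	false	NONE
FANCI	FANCONI	DOMINANT	false	NONE
FANCL	FANCONI	DOMINANT	false	NONE
FANCM	FANCONI	DOMINANT	false	NONE
SLX4	FANCONI	DOMINANT	false	NONE
UBE2T	FANCONI	DOMINANT	false	NONE
ATM	CHECKPOINT	DOMINANT	false	NONE
ATR	CHECKPOINT	DOMINANT	false	NONE
ATRIP	CHECKPOINT	DOMINANT	false	NONE
CDK12	CHECKPOINT	DOMINANT	false	NONE
CHEK1	CHECKPOINT	DOMINANT	false	NONE
CHEK2	CHECKPOINT	DOMINANT	false	NONE
CLSPN	CHECKPOINT	DOMINANT	false	NONE
HUS1	CHECKPOINT	DOMINANT	false	NONE
MDC1	CHECKPOINT	DOMINANT	false	NONE
RAD1	CHECKPOINT	DOMINANT	false	NONE
RAD17	CHECKPOINT	DOMINANT	false	NONE
RAD9A	CHECKPOINT	DOMINANT	false	NONE
TIMELESS	CHECKPOINT	DOMINANT	false	NONE
TIPIN	CHECKPOINT	DOMINANT	false	NONE
TOPBP1	CHECKPOINT	DOMINANT	false	NONE
TP53	CHECKPOINT	DOMINANT	true	NONE
TP53BP1	CHECKPOINT	DOMINANT	false	NONE
WEE1	CHECKPOINT	DOMINANT	false	NONE
DDB1	NER	DOMINANT	false	NONE
DDB2	NER	DOMINANT	false	NONE
ERCC1	NER	DOMINANT	false	NONE
ERCC2	NER	DOMINANT	false	NONE
ERCC3	NER	DOMINANT	false	NONE
ERCC4	NER	DOMINANT	false	NONE
ERCC5	NER	DOMINANT	false	NONE
ERCC6	NER	DOMINANT	false	NONE
ERCC8	NER	DOMINANT	false	NONE
GTF2H5	NER	DOMINANT	false	NONE
POLH	NER	DOMINANT	false	NONE
XAB2	NER	DOMINANT	false	NONE
XPA	NER	DOMINANT	false	NONE
XPC	NER	DOMINANT	false	NONE
EPCAM	MMR	DOMINANT	false	NONE
MLH1	MMR	DOMINANT	true	IMMUNOTHERAPY
MLH3	MMR	DOMINANT	false	NONE
MSH2	MMR	DOMINANT	true	IMMUNOTHERAPY
MSH3	MMR	DOMINANT	false	NONE
MSH6	MMR	DOMINANT	true	IMMUNOTHERAPY
PMS1	MMR	DOMINANT	false	NONE
PMS2	MMR	DOMINANT	true	IMMUNOTHERAPY
ACD	OTHER	DOMINANT	false	NONE
AIP	OTHER	DOMINANT	false	NONE
ALK	OTHER	DOMINANT	false	NONE
APC	OTHER	DOMINANT	true	NONE
APEX1	OTHER	DOMINANT	false	NONE
AXIN2	OTHER	DOMINANT	false	NONE
BMPR1A	OTHER	DOMINANT	true	NONE
BUB1B	OTHER	DOMINANT	false	NONE
CDC73	OTHER	DOMINANT	false	NONE
CDH1	OTHER	DOMINANT	false	NONE
CDK4	OTHER	DOMINANT	false	NONE
CDKN2A	OTHER	DOMINANT	false	NONE
CEBPA	OTHER	DOMINANT	false	NONE
CTNNA1	OTHER	DOMINANT	false	NONE
DCLRE1C	OTHER	DOMINANT	false	NONE
DICER1	OTHER	DOMINANT	false	NONE
ETV6	OTHER	DOMINANT	false	NONE
EXO1	OTHER	DOMINANT	false	NONE
FH	OTHER	DOMINANT	false	NONE
FLCN	OTHER	DOMINANT	false	NONE
GALNT12	OTHER	DOMINANT	false	NONE
GATA2	OTHER	DOMINANT	false	NONE
GREM1	OTHER	DOMINANT	false	NONE
HNF1A	OTHER	DOMINANT	false	NONE
HOXB13	OTHER	DOMINANT	false	NONE
KIT	OTHER	DOMINANT	false	NONE
KLLN	OTHER	DOMINANT	false	NONE
LIG1	OTHER	DOMINANT	false	NONE
LIG3	OTHER	DOMINANT	false	NONE
LIG4	OTHER	DOMINANT	false	NONE
MAX	OTHER	DOMINANT	false	NONE
MBD4	OTHER	DOMINANT	false	NONE
MEN1	OTHER	DOMINANT	true	NONE
MET	OTHER	DOMINANT	false	NONE
MITF	OTHER	DOMINANT	false	NONE
MUTYH	OTHER	RECESSIVE	true	NONE
NEIL1	OTHER	DOMINANT	false	NONE
NF1	OTHER	DOMINANT	false	NONE
NF2	OTHER	DOMINANT	true	NONE
NHEJ1	OTHER	DOMINANT	false	NONE
NTHL1	OTHER	RECESSIVE	false	NONE
OGG1	OTHER	DOMINANT	false	NONE
PALLD	OTHER	DOMINANT	false	NONE
PARP1	OTHER	DOMINANT	false	NONE
PDGFRA	OTHER	DOMINANT	false	NONE
PHOX2B	OTHER	DOMINANT	false	NONE
PNKP	OTHER	DOMINANT	false	NONE
POLB	OTHER	DOMINANT	false	NONE
POLD1	OTHER	DOMINANT	false	NONE
POLD3	OTHER	DOMINANT	false	NONE
POLE	OTHER	DOMINANT	false	NONE
POT1	OTHER	DOMINANT	false	NONE
PRKAR1A	OTHER	DOMINANT	false	NONE
PRKDC	OTHER	DOMINANT	false	NONE
PTCH1	OTHER	DOMINANT	false	NONE
PTEN	OTHER	DOMINANT	true	NONE
RB1	OTHER	DOMINANT	true	NONE
RET	OTHER	DOMINANT	true	NONE
RNF43	OTHER	DOMINANT	false	NONE
RPA1	OTHER	DOMINANT	false	NONE
RTEL1	OTHER	DOMINANT	false	NONE
RUNX1	OTHER	DOMINANT	false	NONE
SDHA	OTHER	DOMINANT	false	NONE
SDHAF2	OTHER	DOMINANT	true	NONE
SDHB	OTHER	DOMINANT	true	NONE
SDHC	OTHER	DOMINANT	true	NONE
SDHD	OTHER	DOMINANT	true	NONE
SEC23B	OTHER	DOMINANT	false	NONE
SMAD4	OTHER	DOMINANT	true	NONE
SMAD9	OTHER	DOMINANT	false	NONE
SMARCA4	OTHER	DOMINANT	false	NONE
SMARCB1	OTHER	DOMINANT	false	NONE
SMARCE1	OTHER	DOMINANT	false	NONE
SPRTN	OTHER	DOMINANT	false	NONE
STK11	OTHER	DOMINANT	true	NONE
SUFU	OTHER	DOMINANT	false	NONE
TERT	OTHER	DOMINANT	false	NONE
TINF2	OTHER	DOMINANT	false	NONE
TMEM127	OTHER	DOMINANT	false	NONE
TSC1	OTHER	DOMINANT	true	NONE
TSC2	OTHER	DOMINANT	true	NONE
VHL	OTHER	DOMINANT	true	NONE
WT1	OTHER	DOMINANT	true	NONE
XRCC1	OTHER	DOMINANT	false	NONE
XRCC4	OTHER	DOMINANT	false	NONE
XRCC5	OTHER	DOMINANT	false	NONE
XRCC6	OTHER	DOMINANT	false	NONE
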