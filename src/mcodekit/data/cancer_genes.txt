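# Gene symbols used by the synthetic cohort generator (one per line, HGNC symbols).
# Editable without code change; common somatic/germline cancer driver genes.
EGFR
TP53
KRAS
BRAF
PIK3CA
APC
PTEN
RB1
NF1
ATM
BRCA1
BRCA2
ALK
ROS1
MET
ERBB2
KIT
PDGFRA
IDH1
IDH2
FLT3
NPM1
JAK2
NRAS
HRAS
CDKN2A
SMAD4
STK11
VHL
MLH1
MSH2
MSH6
PMS2
POLE
CTNNB1
FBXW7
ARID1A
KMT2D
NOTCH1
MYC
MYCN
CCND1
CDK4
CDK6
ESR1
AR
GNAQ
GNA11
SF3B1
U2AF1
DNMT3A
TET2
ASXL1
EZH2
RUNX1
CEBPA
WT1
RET
NTRK1
MDM2
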