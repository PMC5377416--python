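ABCA1
ABCC10
ABCC11
AFAP1L2
ANG
APEX1
ARAF
ATP7B
BMP7
BNIP3
BRCA1
BTG2
C1ORF43
CARD10
CCL3
CCNA2
CCNE2
CCT3
CD40LG
CDKN3
CFH
CHD1L
CHEK1
CHFR
CKAP4
CNDP2
COMMD7
COPS8
CRY1
CTTN
CYP2E1
DENND2D
EGFR
EIF5A2
EPHA5
ERBB4
FADD
FAS
FBXO8
FGB
GALNT10
GNB2L1
GPX3
GTF2I
HAS2
HNRNPD
IFI6
IL3
IRAK1
JMJD1A
KIF18A
KISS1
KRT23
LAMA2
LCK
LIN28
LYZ
MARK2
MCPH1
MMP11
MST1R
MTA2
MVD
NFE2
NME1
NODAL
NOX4
NP
PA2G4
PBLD
PDGFRB
PER3
PFTK1
PIWIL4
PLAUR
PLK2
PMS1
PPP2R4
PRDX4
PSMD10
RAC2
ROCK1
SLC1A5
SMAD4
SNRPE
SORT1
TFF3
TGIF1
TLR3
TNFRSF13B
TPT1
TRAF2
TRAF6
TRAV10
TSPAN1
UHRF1
VIM
VWCE
WASF2
WNT3
XPC
XRCC1
ZDHHC2
ZNF23
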