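# Genes known to be recurrently affected by focal deletions (42 genes).
CDKN2A
CDKN2B
FHIT
WWOX
PTPRD
MACROD2
PARK2
RB1
LRP1B
PDE4D
RBFOX1
PTEN
CSMD1
DMD
OPCML
NTM
ETV6
NF1
ATM
PRKG1
PAX5
TP53
PTPRN2
APC
NEGR1
GPC6
RYR2
MAGI2
CNTNAP2
NAALADL2
ANKS1B
PARD3B
SNTG1
CDH13
DLG2
SDK1
MAP2K4
DSCAM
TMPRSS2
ERG
SMAD4
DCC
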