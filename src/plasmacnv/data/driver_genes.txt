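# Amplification driver genes: default set of 30 genes recurrently amplified
# across cancers.  Replace or extend with a fuller curated driver list
# (tyrosine kinases, amplified-and-overexpressed census genes, tumour-type
# specific and druggable targets) for production use.
MYC
CCND1
ERBB2
CDK4
NKX2-1
MDM2
EGFR
MCL1
FGFR1
KRAS
CCNE1
CRKL
HMGA2
TERT
PRKCI
IGF1R
MYCL
MYCN
CDK6
BCL2L1
MYB
MET
JUN
BIRC2
YAP1
PDGFRA
KIT
PIK3CA
MDM4
AR
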