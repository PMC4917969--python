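# Convenience gene track: approximate hg19 gene-body coordinates for a small
# set of recurrent prostate-cancer genes; for simulations and demos only.
chr5	83538851	83680612	EDIL3
chr7	55086725	55324313	EGFR
chr8	38268656	38326352	FGFR1
chr8	128748315	128753680	MYC
chr9	21967751	21995300	CDKN2A
chr10	43572475	43625799	RET
chr10	89623195	89728532	PTEN
chr11	69455873	69469242	CCND1
chr13	48877887	49056122	RB1
chr17	7571720	7590868	TP53
chr17	37844393	37884915	ERBB2
chr21	39751949	40033704	ERG
chr21	42836478	42903043	TMPRSS2
chrX	66764465	66950461	AR
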