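motif_id	iupac	tf_family
Gbox_core	CACGTG	bZIP
ABRE_like	ACGTGKC	bZIP
TGA_box	TGACGT	bZIP
Hexamer	ACGTCA	bZIP
GCC_box	AGCCGCC	AP2
DRE_core	RCCGAC	AP2
ERE_like	AWTTCAAA	AP2
CBF_site	GTCGAC	AP2
MYB_AC1	ACCWACC	MYB
MYB_AC2	ACCWWCC	MYB
MYB_PLANT	MACCWAMC	MYB
MBS_drought	CAACTG	MYB
MYB_core	YAACKG	MYB
CArG_box	CCWWWWWWGG	MADS
MADS_short	CCAWWWWTGG	MADS
SQUAMOSA	CCAAAAATGG	MADS
NAC_SNBE	TTGCGTGT	NAC
NAC_core	CATGTG	NAC
CUC_site	CACGCAA	NAC
AuxRE	TGTCTC	ARF
AuxRE_rev	TGTCGG	ARF
Wbox	TTGACC	WRKY
Wbox_alt	TTGACT	WRKY
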