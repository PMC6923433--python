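name	consensus	category
ABRE	ACGTG	hormone
ARE	AAACCA	stress
AuxRE	TGTCTC	hormone
GARE-motif	TCTGTTG	hormone
LTR	CCGAAA	stress
MBS	CAACTG	stress
MeJA-RE	CGTCA	hormone
TC-rich repeat	ATTCTCTAAC	stress
WUN-motif	AAATTTCCT	stress
Box 4	ATTAAT	light
G-box	CACGTG	light
GT1-motif	GGTTAA	light
TCT-motif	TCTTAC	light
Sp1	GGGCGG	light
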