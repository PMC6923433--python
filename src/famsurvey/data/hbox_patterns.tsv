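subfamily	box_index	pattern
FAB2	1	WT(S)AE(K)ENR(H)HG
FAB2	2	DAA(S)DEKRHE
FAD2	1	WV(I)IA(G)HECGHHAFS
FAD2	2	FSWKYS(T)HR(Q)RHHSNTT
FAD2	3	DTHVXHHLFP(S)
FAD3/7/8	1	WALFVLGHDCGHGSFS
FAD3/7/8	2	YHGWRISHRTHHQNHGHH
FAD3/7/8	3	HDIGTHVIHHLFPQIPHYHL
FAD6	1	FFVIGHDCAHRKSFS
FAD6	2	EPWRFKHDRHHAKTN
FAD6	3	HDINVHVPHHISPRS
SLD1	1	GHDSGHH
SLD1	2	WWKCNHNTHHIACNS
SLD1	3	LDGGLQFQIEHHLFPRLPRD
DES1	1	NLFLAIHELSHN
DES1	2	LAFFQKYHLEHHRFQGVDG
DES1	3	IDHVGYHNEHHDFPRIPG
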