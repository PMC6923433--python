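gene_name	locus_id	accession	introns	size_aa	mw_da	pi	subcellular	ortholog	ortholog_locus	subfamily
OsFAD2-1	LOC_Os02g48560	AK061506	1	389	44350.1	8.23	ER	FAD2	AT3G12120	FAD2
OsFAD2-2	LOC_Os07g23430	AK105371	1	470	52845.2	9.35	plasma membrane	FAD2	AT3G12120	FAD2
OsFAD2-3	LOC_Os07g23410	AK070559	1	391	44981.0	9.51	ER	FAD2	AT3G12120	FAD2
OsFAD2-4	LOC_Os07g23390	NA	1	224	24677.1	12.61	plasma membrane	FAD2	AT3G12120	FAD2
OsFAD3-1	LOC_Os11g01340	AK242740	7	385	43902.4	7.48	ER	FAD3	AT2G29980	FAD3/7/8
OsFAD3-2	LOC_Os12g01370	AK071185	7	386	43899.5	8.01	ER	FAD3	AT2G29980	FAD3/7/8
OsFAD6	LOC_Os08g34220	AK060449	9	455	52243.7	9.51	chloroplast	FAD6	AT4G30950	FAD6
OsFAD7	LOC_Os03g18070	AK058242	7	459	50772.1	7.66	chloroplast	FAD7	AT3G11170	FAD3/7/8
OsFAD8	LOC_Os07g49310	AK061531	6	414	47012.0	8.73	chloroplast	FAD8	AT5G05580	FAD3/7/8
OsFAB2-1	LOC_Os01g65830	AK059526	1	382	42942.9	7.10	chloroplast	FAB2.1	AT1G43800	FAB2
OsFAB2-2	LOC_Os01g69080	AK058979	2	401	45320.7	7.07	chloroplast	FAB2.2	AT2G43710	FAB2
OsFAB2-3	LOC_Os02g30200	AK069683	3	388	42513.3	7.02	chloroplast	FAB2.2	AT2G43710	FAB2
OsFAB2-4	LOC_Os03g30950	AK070282	1	419	45365.5	7.94	chloroplast	FAB2.4	AT3G02620	FAB2
OsFAB2-5	LOC_Os04g31070	AK065340	2	391	44341.4	7.01	chloroplast	FAB2.2	AT2G43710	FAB2
OsFAB2-6	LOC_Os03g53010	NA	0	264	30087.6	10.47	mitochondrion	FAB2.2	AT2G43710	FAB2
OsFAB2-7	LOC_Os06g30780	NA	0	190	22534.2	12.46	mitochondrion	FAB2.4	AT3G02620	FAB2
OsFAB2-8	LOC_Os08g09950	AK105852	1	423	46491.2	7.98	chloroplast	FAB2.3	AT3G02610	FAB2
OsFAB2-9	LOC_Os08g10010	AK241294	1	405	44829.0	7.41	mitochondrion	FAB2.3	AT3G02610	FAB2
OsDES1	LOC_Os02g42660	AK101968	1	329	37868.6	8.93	plasma membrane	DES1	AT4G04930	DES1
OsSLD1	LOC_Os09g16920	AK058543	0	467	51723.8	8.55	plasma membrane	SLD1.1	AT2G46210	SLD1
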