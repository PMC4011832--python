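or_name	agonist	copies_mean	copies_sd	n_expressing
OR1A1	Dihydrojasmone	7	8	12
OR1A2	Citronellal	0.6	1	1
OR1C1	Linalool	77	64	26
OR1D2	Bourgeonal	146	117	26
OR1G1	1-nonanol	14	48	11
OR2A25	Geranyl acetate	103	95	26
OR2AG1	Amyl butyrate	157	94	26
OR2B11	Coumarin	365	615	26
OR2C1	Octanethiol	78	71	26
OR2J2	1-octanol	37	46	23
OR2J3	Cis-3-hexen-1-ol	82	118	25
OR2M7	Citronellol	2	4	4
OR2W1	1-octanol	6	13	7
OR3A1	Helional	26	33	23
OR4D6	beta-ionone	8	13	11
OR4D9	beta-ionone	190	216	26
OR4E2	Amyl acetate	17	15	20
OR4Q3	Eugenol	50	50	22
OR5A1	beta-ionone	737	1018	25
OR5A2	beta-ionone	435	386	26
OR5AN1	Muscone	377	290	26
OR5D18	Eugenol	0.7	1	0
OR5K1	Eugenol methyl ether	598	412	26
OR5P3	(+)-carvone	752	642	26
OR6P1	Anisaldehyde	29	59	16
OR7C1	Androstadienone	1108	849	26
OR7D4	Androstenone	74	98	24
OR8B3	(+)-carvone	37	50	22
OR8D1	4,5-dimethyl-3-hydroxy-2,5-dihydrofuran-2-one	558	572	25
OR8K3	(+)-menthol	66	80	21
OR10A6	3-phenyl propyl propionate	286	273	26
OR10G3	Ethyl vanillin	487	443	25
OR10G4	Ethyl vanillin	29	35	22
OR10G7	Eugenol	13	12	19
OR10G9	Ethyl vanillin	2	3	3
OR10J5	Lyral	10	9	19
OR11A1	2-ethyl fenchol	324	266	26
OR11H4	Isovaleric acid	64	51	26
OR11H6	Isovaleric acid	15	12	22
OR11H7P	Isovaleric acid	142	100	26
OR51E1	Nonanoic acid	170	266	26
OR51E2	Propionic acid	16	20	20
OR51L1	4-allylphenylacetate	35	33	22
OR52D1	Ethyl isobutyrate	317	272	26
OR56A1	Decyl aldehyde	39	41	26
OR56A4	Decyl aldehyde	37	39	25
OR56A5	Decyl aldehyde	9	11	15
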