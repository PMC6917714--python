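strain	species	source	accession	size_mb	n_contigs	n_orfs	n_rrna
Bac48	B. paralicheniformis	mangrove_mud	CP023666	4.46	1	4366	24
Bac84	B. paralicheniformis	microbial_mat	CP023665	4.38	1	4306	24
Bac44	B. foraminis	mangrove_mud	CP033044-CP033045	5.43	2	5639	34
Bac144	B. marisflavi	barren_soil	CP033051	4.59	1	4440	39
Bac94	B. halosaccharovorans	microbial_mat	CP033043	5.23	1	5055	58
Bac111	B. vallismortis	microbial_mat	CP033052	3.96	1	3899	30
Bac57	B. amyloliquefaciens	mangrove_mud	CP033053-CP033054	4.23	2	4107	27
Bac330	V. dokdonensis	mangrove_mud	CP033048	4.46	1	4221	18
Bac332	Virgibacillus sp.	mangrove_mud	CP033046-CP033047	4.56	2	4492	18
Bac324	V. halodenitrificans	mangrove_mud	CP033049-CP033050	4.06	2	4306	24
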