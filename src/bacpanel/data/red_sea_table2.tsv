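strain	gi_percent	prophage_percent	biosynthetic_genes_in_gi	assigned_product	cluster_types
Bac48	5.05	2.43	38		terpene;trans-AT PKS/NRPS
Bac84	5.77	3.20	21		terpene;bacteriocin
Bac44	2.89	2.75	0
Bac144	5.29	0.61	53		terpene
Bac94	4.31	0.28	19		terpene
Bac111	6.19	0.88
Bac57	9.91	7.04	46	Bacillaene	phosphonate;trans-AT PKS/NRPS;lantipeptide;NRPS
Bac330	6.95	3.11	43		NRPS;NRPS-PKS
Bac332	9.39	4.11	72		trans-AT PKS/NRPS;NRPS
Bac324	5.19	3.68	0
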