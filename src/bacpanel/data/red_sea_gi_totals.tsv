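quantity	value
gi_bp_total	2737911
n_genomes	10
gi_bp_min	172668
gi_bp_max	434257
reference_gi_mean_percent	5.6
q3_low	5.05
q3_high	6.69
q4_low	6.89
q4_high	19.48
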