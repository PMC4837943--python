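taxon	DGDG_percent	MGDG_percent	printed_ratio	ratio_consistent
B_dodgei	53.6	46.4	1.2	1
B_tenuissima	54.2	45.8	1.2	1
P_aciculiferum	52.9	47.1	1.1	1
T_coronata	55.1	44.9	1.2	1
C_cornutum	80.0	20.0	4.0	1
G_palustre	65.6	34.4	1.6	0
J_applanata	62.9	37.1	1.7	1
P_willei	72.6	27.4	2.6	1
P_cinctum	62.1	37.9	1.6	1
P_gatunense	68.2	31.8	2.1	1
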