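species	group	B_tenuissima	B_dodgei	P_aciculiferum	T_coronata	C_cornutum	G_palustre	J_applanata	P_willei	P_cinctum	P_gatunense
DGDG 36:9	group1	79.1	82.3	81.1	77.4	1.4	17.9	n.d.	1.7	13.0	10.8
DGDG 38:9	group2	n.d.	n.d.	n.d.	0.4	65.9	24.2	53.6	89.6	76.9	61.9
DGDG 38:10	group2	n.d.	n.d.	n.d.	n.d.	9.4	6.4	3.3	4.3	n.d.	2.7
MGDG 36:9	group1	29.7	45.1	42.2	43.3	2.9	9.5	n.d.	6.4	n.d.	n.d.
MGDG 38:9	group2	2.2	n.d.	n.d.	4.2	45.5	24.4	27.0	33.9	36.1	37.3
MGDG 38:10	group2	4.4	n.d.	n.d.	3.0	27.5	27.8	13.2	39.4	11.8	12.1
TGDG 32:1	group2	7.6	14.1	7.9	5.1	100.0	34.2	85.1	63.6	70.1	72.9
DGCC 36:6	group1	51.9	60.5	46.6	39.1	3.5	28.7	48.7	11.1	11.9	5.7
SQDG 34:1	group2	13.5	7.3	n.d.	4.5	30.8	85.1	38.7	88.9	81.6	77.9
PE 32:1	group2	n.d.	n.d.	n.d.	n.d.	n.d.	41.6	34.3	64.1	n.d.	30.1
PE 34:2	group2	n.d.	n.d.	n.d.	n.d.	n.d.	27.8	37.9	35.9	100.0	41.1
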