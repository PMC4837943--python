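class	total_carbons	total_double_bonds	chains
MGDG	34	1	16:0/18:1
MGDG	34	4	16:1/18:3
MGDG	36	6	18:3/18:3
MGDG	36	8	18:4/18:4
MGDG	36	9	18:5/18:4
MGDG	36	10	18:5/18:5
MGDG	38	9	20:5/18:4
MGDG	38	10	20:5/18:5
MGDG	40	10	20:5/20:5
DGDG	34	1	16:0/18:1
DGDG	34	4	16:1/18:3
DGDG	36	6	18:3/18:3
DGDG	36	8	18:4/18:4
DGDG	36	9	18:5/18:4
DGDG	36	10	18:5/18:5
DGDG	38	9	20:5/18:4
DGDG	38	10	20:5/18:5
DGDG	40	10	20:5/20:5
DGDG	34	2	16:1/18:1
DGDG	36	2	18:1/18:1
DGDG	36	4	18:1/18:3
DGDG	38	6	16:0/22:6
TGDG	32	0	16:0/16:0
TGDG	32	1	16:0/16:1
TGDG	34	1	16:0/18:1
TGDG	34	2	16:1/18:1
TGDG	34	4	16:1/18:3
TGDG	36	2	18:1/18:1
TGDG	36	6	18:3/18:3
TGDG	36	8	18:4/18:4
TGDG	36	9	18:5/18:4
TGDG	36	10	18:5/18:5
SQDG	28	0	14:0/14:0
SQDG	30	0	14:0/16:0
SQDG	30	1	14:0/16:1
SQDG	32	0	16:0/16:0
SQDG	32	1	16:0/16:1
SQDG	32	2	16:1/16:1
SQDG	34	1	16:0/18:1
SQDG	34	2	16:1/18:1
SQDG	34	3	16:0/18:3
DGCC	28	0	14:0/14:0
DGCC	30	0	14:0/16:0
DGCC	30	1	14:0/16:1
DGCC	32	0	16:0/16:0
DGCC	32	1	16:0/16:1
DGCC	32	2	16:1/16:1
DGCC	32	3	14:0/18:3
DGCC	32	4	14:0/18:4
DGCC	32	5	14:0/18:5
DGCC	34	0	16:0/18:0
DGCC	34	1	16:0/18:1
DGCC	34	2	16:1/18:1
DGCC	34	3	16:0/18:3
DGCC	34	6	16:1/18:5
DGCC	42	11	20:5/22:6
DGCC	36	1	18:0/18:1
DGCC	36	2	18:1/18:1
DGCC	36	3	18:0/18:3
DGCC	36	4	18:1/18:3
DGCC	36	6	14:0/22:6
DGCC	36	8	18:4/18:4
DGCC	36	9	18:5/18:4
DGCC	36	10	18:5/18:5
DGCC	38	6	16:0/22:6
DGCC	40	6	18:0/22:6
DGCC	40	7	18:1/22:6
DGCC	40	9	18:3/22:6
DGCC	40	11	18:5/22:6
DGCC	44	12	22:6/22:6
PC	32	0	16:0/16:0
PC	32	1	16:0/16:1
PC	34	1	16:0/18:1
PC	34	3	16:0/18:3
PC	36	6	14:0/22:6
PC	36	7	18:3/18:4
PC	36	8	18:4/18:4
PC	36	9	18:5/18:4
PC	36	10	18:5/18:5
PC	38	6	16:0/22:6
PC	38	8	18:3/20:5
PC	38	9	18:4/20:5
PC	38	10	18:5/20:5
PC	40	6	18:0/22:6
PC	40	9	18:3/22:6
PC	40	10	18:4/22:6
PC	40	11	18:5/22:6
PC	42	11	20:5/22:6
PC	44	12	22:6/22:6
PG	34	1	16:0/18:1
PG	34	2	16:1/18:1
PG	34	3	16:0/18:3
PE	32	1	16:0/16:1
PE	34	1	16:0/18:1
PE	34	2	16:1/18:1
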