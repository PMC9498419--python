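test_id	kind	consistent_144	inconsistent_144	consistent_120	inconsistent_120
Trio_1	trio	142	2	120	0
Trio_2	trio	139	5	120	0
Trio_3	trio	142	2	120	0
Trio_4	trio	143	1	120	0
Trio_5	trio	143	1	120	0
Trio_6	trio	143	1	120	0
Trio_7	trio	141	3	120	0
Trio_8	trio	141	3	120	0
Trio_9	trio	143	1	120	0
Trio_10	trio	140	4	120	0
Trio_11	trio	140	4	120	0
Trio_12	trio	141	3	120	0
Trio_13	trio	141	3	120	0
Trio_14	trio	141	3	120	0
Trio_15	trio	143	1	120	0
Trio_16	trio	141	3	120	0
Trio_17	trio	144	0	120	0
Trio_18	trio	140	4	120	0
Trio_19	trio	141	3	120	0
Trio_20	trio	143	1	120	0
Trio_21	trio	144	0	120	0
Trio_22	trio	142	2	120	0
Trio_23	trio	142	2	120	0
Trio_24	trio	142	2	120	0
Trio_25	trio	142	2	120	0
Trio_26	trio	142	2	120	0
Trio_27	trio	141	3	120	0
Trio_28	trio	141	3	120	0
Trio_29	trio	141	3	120	0
Pseudo-Trio_1	pseudo_trio	108	36	91	29
Pseudo-Trio_2	pseudo_trio	110	34	88	32
Pseudo-Trio_3	pseudo_trio	112	32	91	29
Pseudo-Trio_4	pseudo_trio	111	33	93	27
Pseudo-Trio_5	pseudo_trio	108	36	90	30
Half-pseudo-Trio_1	half_pseudo_trio	123	21	102	18
Half-pseudo-Trio_2	half_pseudo_trio	110	34	95	25
Half-pseudo-Trio_3	half_pseudo_trio	119	25	99	21
Half-pseudo-Trio_4	half_pseudo_trio	116	28	97	23
Half-pseudo-Trio_5	half_pseudo_trio	126	18	105	15
Parent-Foal_1	parent_foal	143	1	120	0
Parent-Foal_2	parent_foal	144	0	120	0
Parent-Foal_3	parent_foal	142	2	120	0
Parent-Foal_4	parent_foal	143	1	120	0
Parent-Foal_5	parent_foal	144	0	120	0
Pseudo-parent-Foal_1	pseudo_parent_foal	132	12	109	11
Pseudo-parent-Foal_2	pseudo_parent_foal	128	16	108	12
Pseudo-parent-Foal_3	pseudo_parent_foal	131	13	110	10
Pseudo-parent-Foal_4	pseudo_parent_foal	132	12	110	10
Pseudo-parent-Foal_5	pseudo_parent_foal	136	8	114	6
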