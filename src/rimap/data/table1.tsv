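mirna	eqtl_chr	eqtl_pos_mb	ci_lo_mb	ci_hi_mb	lod	p_genomewide	fdr	cis_trans
mmu-miR-8114	1	154.3	152.9	154.9	10.11	0.0010	0.0251	C
mmu-miR-32-3p	1	171.8	171.1	174.1	5.51	0.0010	0.0251	T
mmu-miR-1981-3p	1	187.2	183	188.7	7.63	0.0010	0.0251	C
mmu-miR-205-5p	1	193.6	192.5	193.6	6.38	0.0010	0.0251	C
mmu-miR-669o-5p	2	9.8	5.6	10.9	5.32	0.0020	0.0463	C
mmu-miR-467e-5p	2	10.6	3.2	10.9	5.49	0.0010	0.0251	C
mmu-miR-669a-5p	2	10.6	8.1	10.9	6.29	0.0010	0.0251	C
mmu-miR-297b-5p	2	10.6	10.6	10.9	5.83	0.0020	0.0463	C
mmu-miR-7674-5p	2	32.8	32.8	34.6	6.77	0.0010	0.0251	C
mmu-miR-466q	3	28.4	28	28.9	18.86	0.0010	0.0251	C
novel:chr4_9669	4	43.1	32	43.1	12.41	0.0010	0.0251	C
novel:chr4_11381	4	87.1	87.1	87.2	23.47	0.0010	0.0251	C
mmu-miR-9769-3p	7	30.6	30.6	30.6	25.92	0.0010	0.0251	C
mmu-miR-5121	7	43.5	40.3	45.5	17.25	0.0010	0.0251	C
mmu-miR-7057-5p	7	64.6	57	67.1	24.43	0.0010	0.0251	C
novel:chr8_23508	8	125.5	125.4	125.6	21.89	0.0010	0.0251	C
novel:chr9_24385	9	77.3	77.3	77.3	19.99	0.0010	0.0251	C
novel:chr4_10452	9	100.3	94	113.4	5.78	0.0010	0.0251	T
novel:chr10_26214	10	4.8	4	5.6	32.53	0.0010	0.0251	C
mmu-miR-6905-5p	10	25.3	24.8	25.9	12.75	0.0010	0.0251	C
novel:chr10_26328	10	25.3	24.8	25.9	20.74	0.0010	0.0251	C
mmu-miR-1934-5p	11	69.0	67.8	69.7	20.39	0.0010	0.0251	C
mmu-miR-193a-3p	11	74.3	74.3	79.5	7.29	0.0010	0.0251	T
mmu-miR-8103	11	95.1	95.1	99.6	8.04	0.0010	0.0251	C
mmu-miR-152-5p	11	96.2	93.4	103.4	6.33	0.0010	0.0251	C
mmu-miR-677-5p	11	98.3	96.4	101	20.81	0.0010	0.0251	T
mmu-miR-5621-5p	11	115.6	115.4	116	25.18	0.0010	0.0251	C
mmu-miR-208b-3p	14	54.7	54.6	55	9.32	0.0010	0.0251	C
novel:chr15_40280	15	94.8	94.8	95.5	8.10	0.0010	0.0251	C
mmu-miR-6516-5p	16	45.7	45.7	51.5	5.94	0.0020	0.0463	T
mmu-miR-381-5p	16	45.8	45.7	51.5	5.59	0.0010	0.0251	T
mmu-miR-6929-3p	19	30.0	29.3	30.5	7.46	0.0010	0.0251	T
mmu-miR-3086-5p	19	30.2	29.3	30.5	5.06	0.0010	0.0251	T
mmu-miR-201-5p	X	66.6	65.4	66.6	8.63	0.0010	0.0251	C
mmu-miR-465c-5p	X	66.6	65.4	82.2	5.44	0.0010	0.0251	C
mmu-miR-547-3p	X	66.6	65.4	66.6	9.58	0.0010	0.0251	C
mmu-miR-871-3p	X	66.6	49	67.4	6.28	0.0010	0.0251	C
mmu-miR-881-3p	X	66.6	65.4	67.4	6.13	0.0010	0.0251	C
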