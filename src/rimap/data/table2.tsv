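mirna	chr	start_bp	end_bp	mirna_type	annotation	conservation	icc	n_targets
mmu-miR-8114	1	153899989	153900009	I	A	0.064	0.71	0
mmu-miR-32-3p	4	56895232	56895252	N	A	1.000	0.31	0
mmu-miR-1981-3p	1	184822409	184822429	I	A	0.062	0.56	0
mmu-miR-205-5p	1	193507503	193507524	N	A	1.000	0.25	31
mmu-miR-669o-5p	2	10514318	10514340	N	A	0.972	0.16	8
mmu-miR-467e-5p	2	10505731	10505752	N	A	NA	0.35	12
mmu-miR-669a-5p	2	10510185	10510208	N	A	NA	0.26	13
mmu-miR-297b-5p	2	10511686	10511707	N	A	0.727	0.09	147
mmu-miR-7674-5p	2	32050946	32050969	I	A	0.093	0.40	0
mmu-miR-466q	3	28419988	28420007	N	A	NA	0.80	175
novel:chr4_9669	4	41640264	41640319	N	N	0.525	0.59	0
novel:chr4_11381	4	87071780	87071841	I	N	0.264	0.88	0
mmu-miR-9769-3p	7	30552871	30552892	N	A	0.820	0.89	0
mmu-miR-5121	7	45126925	45126945	N	A	0.799	0.72	17
mmu-miR-7057-5p	7	66381702	66381719	I	A	0.000	0.85	0
novel:chr8_23508	8	125837774	125837841	N	N	0.003	0.84	0
novel:chr9_24385	9	74966743	74966804	I	N	0.474	0.75	0
novel:chr4_10452	4	132310004	132310065	N	N	0.822	0.56	0
novel:chr10_26214	10	4092814	4092873	I	N	0.002	0.87	0
mmu-miR-6905-5p	10	24910669	24910691	I	A	0.000	0.62	0
novel:chr10_26328	10	25416000	25416061	N	N	0.923	0.71	0
mmu-miR-1934-5p	11	69663055	69663077	N	A	0.000	0.60	13
mmu-miR-193a-3p	11	79712009	79712030	I	A	1.000	0.33	8
mmu-miR-8103	11	97063829	97063849	N	A	0.001	0.33	0
mmu-miR-152-5p	11	96850400	96850423	N	A	0.996	0.48	0
mmu-miR-677-5p	10	128085291	128085312	I	A	0.858	0.76	51
mmu-miR-5621-5p	11	115795824	115795846	N	A	0.003	0.83	0
mmu-miR-208b-3p	14	54975710	54975731	N	A	1.000	0.38	12
novel:chr15_40280	15	95488968	95489024	N	N	0.001	0.38	0
mmu-miR-6516-5p	1	117077370	117077391	N	A	0.974	0.51	0
mmu-miR-381-5p	12	109726829	109726851	I	A	1.000	0.31	0
mmu-miR-6929-3p	11	101419187	101419209	I	A	0.165	0.25	0
mmu-miR-3086-5p	19	58911725	58911744	N	A	0.012	0.35	9
mmu-miR-201-5p	X	67988135	67988156	I	A	0.001	0.48	31
mmu-miR-465c-5p	X	66832566	66832587	N	A	0.079	0.39	24
mmu-miR-547-3p	X	67988383	67988403	I	A	0.025	0.50	14
mmu-miR-871-3p	X	66810438	66810460	N	A	0.001	0.43	5
mmu-miR-881-3p	X	66801954	66801975	N	A	0.045	0.50	28
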