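dose_gy	n_cells	d0	d1	d2	d3	d4	d5
0	37954	37878	76	0	0	0	0
0.1	24220	24064	156	0	0	0	0
0.25	19789	19474	313	2	0	0	0
0.5	16322	15710	599	13	0	0	0
0.75	14367	13459	885	21	2	0	0
1	13028	11690	1278	51	8	1	0
2	8212	5813	1977	387	31	4	0
3	5645	2674	2017	725	191	32	6
4	4516	1293	1662	1019	348	139	55
5	3047	407	986	733	495	252	174
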