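dose_gy	n_cells	d0	d1	d2	d3	d4	d5
0	40792	38550	2209	30	3	0	0
0.1	27245	25151	2004	82	8	0	0
0.25	22665	20936	1642	84	3	0	0
0.5	18160	16454	1601	97	8	0	0
0.75	16605	14605	1869	121	9	1	0
1	14641	12619	1862	142	18	0	0
2	9943	7641	2021	234	42	4	1
3	7137	4766	1895	437	28	10	1
4	6076	3306	1912	763	74	19	2
5	3978	1612	1541	547	206	60	12
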