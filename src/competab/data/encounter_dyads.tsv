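dyad_id	pop_1	weight_1	age_1	wins_1	pop_2	weight_2	age_2	wins_2
1	CB	33.64	288	28	MC	19.89	313	2
2	CB	34.02	306	0	MC	20.57	301	0
3	CB	34.75	318	0	MC	21.64	313	24
4	CB	36.56	326	27	MC	21.84	401	0
5	CB	36.77	315	39	MC	24.08	331	0
6	CB	23.91	326	0	MC	27.94	309	28
7	CB	25.06	293	12	MC	28.43	311	1
8	CB	25.38	326	25	MC	31.17	309	1
9	CB	26.60	319	0	MC	33.36	309	24
10	CB	27.00	344	22	MC	35.83	383	2
11	CB	24.53	319	0	MC	24.27	382	0
12	CB	28.21	293	8	MC	24.73	383	0
13	CB	28.62	316	6	MC	25.62	331	0
14	CB	28.70	288	11	MC	26.65	343	0
15	CB	28.71	290	11	MC	26.89	401	0
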