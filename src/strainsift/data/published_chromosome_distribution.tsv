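chromosome	CC-124	CC-125	isoloM	isoloP
1	0.73	5.22	0.38	0.41
2	1.24	7.90	0.87	0.84
3	8.48	5.92	9.85	0.49
4	0.72	5.17	0.46	0.44
5	0.65	4.14	0.39	0.42
6	21.60	7.39	27.68	0.85
7	0.64	4.75	0.43	0.46
8	0.97	6.84	0.83	0.98
9	1.02	6.73	0.60	0.64
10	0.52	3.79	0.32	0.35
11	0.43	3.65	0.30	0.34
12	9.69	8.54	11.98	14.08
13	0.52	3.71	0.31	0.32
14	0.60	4.59	0.38	0.44
15	0.81	4.67	0.73	0.85
16	30.73	6.60	39.78	46.71
17	19.45	6.20	3.76	30.29
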