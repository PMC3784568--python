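chromosome	total	unique	coding	nonsynonymous_retained
1	725	151	2	1
2	1158	171	3	2
3	8409	879	181	158
4	715	97	2	2
5	621	80	1	1
6	18111	132	4	3
7	637	136	3	2
8	829	115	3	3
9	955	194	3	2
10	524	103	3	3
11	464	84	2	1
12	9725	495	54	40
13	524	107	3	2
14	580	96	3	2
15	614	53	2	2
16	23936	1979	354	297
17	15256	2160	329	286
Total	91066	7092	954	809
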