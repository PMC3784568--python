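strain	n_changes	unique_pct_floor
CC-124	100737	.
CC-125	13218	.
cnk10	85168	2
isoloM	65437	.
isoloP	56734	.
S1C5	2357347	.
fla18	1537589	2
fla24	72298	1
fla9	83402	2
ida3	84908	2
ift80	39294	13
imp3	91066	7
pf23	22198	11
pf7	67691	2
pf8	73576	1
uni1	151608	21
Total	2557197	.
Total_exclude_imp3	2550105	.
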