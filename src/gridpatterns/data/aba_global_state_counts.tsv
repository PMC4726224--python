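E11.5	E13.5	E15.5	E18.5	P4	P14	P28	n_genes
0	0	0	0	0	0	0	453
1	1	1	1	1	1	1	235
0	1	1	1	1	1	1	86
0	0	0	1	1	1	1	79
0	0	0	0	0	1	0	76
0	0	0	0	0	1	1	73
0	0	0	0	1	1	1	62
0	0	1	1	1	1	1	61
0	0	0	0	1	1	0	41
0	0	0	0	1	0	0	39
0	0	0	1	1	1	0	30
0	0	0	1	0	0	0	29
1	0	1	1	1	1	1	26
0	0	0	1	1	0	0	25
0	0	0	1	0	1	0	22
1	1	1	0	1	1	1	22
0	0	0	0	0	0	1	21
0	0	0	1	0	1	1	20
1	0	0	1	1	1	1	19
1	1	1	1	1	1	0	19
1	0	0	0	1	1	1	15
1	1	1	1	0	1	1	15
0	0	0	0	1	1	1	14
0	0	0	1	1	1	1	14
1	0	0	1	1	1	1	14
1	0	0	0	0	0	0	13
0	1	1	1	1	1	0	12
0	0	0	0	0	0	0	11
1	0	0	0	0	1	0	11
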