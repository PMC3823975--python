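sample_id	marker	pct_bright	pct_bright_n	marker_pct_bright	marker_pct_bright_n	pct_low	pct_low_n	marker_pct_low	marker_pct_low_n
575	CD33	51.3		1.7	2	0.01		100
670	CLL-1	54.4		0.3	1	0.1		4.5
726	CD7	34.5		0.3	3	0
808	none	22.7				0.2
945	CLL-1/CD19	44.6		1.1	2	0.1		86.4
951	CLL-1	51.9		1.5	23	0.1		76.7
966	CD7	58.9				0.5		24.4
1013	CLL-1	22		0.67	15	2.36		15
1016	CD11b	0.25		0		0.28		13
1022	CLL-1	38		0		0
1030	CD22	10		3	2	3.5		6
1034	CLL-1	3		0		0.12		40
1036	CLL-1	20		0		15		25
1047	CD7	5.5		0		0.18		12
1048	CD7	92		0.03		34		12
1057	CD19	7		0		0.15		67
1263	CD33/CD123	84		0		1.7		99
1305	CLL-1	58		3.5	6	0.7		84
1320	CD2	92.2		0		0.6		7.2
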