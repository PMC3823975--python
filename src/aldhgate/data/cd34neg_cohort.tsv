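sample_id	marker	pct_bright	pct_bright_n	marker_pct_bright	marker_pct_bright_n	pct_low	pct_low_n	marker_pct_low	marker_pct_low_n
464	CD56	83.8		0		0
508	CLL-1	35		0		0
813	CLL-1	24.6		0.1	2	0
822	CLL-1	50.4		0		0
1021	CLL-1	75		0		0.89		24
1024	CD7	9		0		2.7	10	0
1027	CLL-1	48				1.9	5
1028	CD7	60		0		0.05		0.44	1
1035	CLL-1	70		0		0.02	14	20	9
1045	CLL-1	14		0		0
1054	CD56	3		0		0
1063	CLL-1	57		0		0.01	8
1276	CLL-1	7.9		0.1		0
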