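chromosome	n_markers	avg_gap_cM	largest_gap_cM
1A	94	1.77	13.73
1B	136	1.77	12.83
1D	77	4.09	25.96
2A	134	1.84	9.33
2B	132	1.93	9.68
2D	84	3.12	25.71
3A	89	2.38	11.03
3B	133	1.66	9.22
3D	36	4.49	17.75
4A	101	1.83	8.91
4B	91	1.64	13.98
4D	52	5.49	41.63
5A	150	1.25	10.63
5B	180	1.57	12.69
5D	100	3.73	37.89
6A	109	2.08	10.24
6B	101	1.59	6.55
6D	59	5.05	23.47
7A	121	2.59	14.83
7B	114	2.14	11.99
7D	84	4.31	25.27
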