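trait	k_all	p_all	presence_all	absence_all	percent_all	k_chrom	p_chrom	presence_chrom	absence_chrom	percent_chrom
arsR	0.016	0.255	22	250	8.1	0.024	0.505	21	198	9.6
merR_convergent	0.014	0.082	52	220	19.1	0.034	0.157	48	171	21.9
merR_divergent	0.019	0.004	143	129	52.6	0.061	0.005	105	114	47.9
merR_multiple	0.060	0.305	5	267	1.8	0.110	0.315	3	216	1.4
merR	0.012	0.152	195	77	71.7	0.034	0.353	153	66	69.9
merP	0.026	0.003	134	138	49.3	0.237	0.001	98	121	44.7
merT	0.012	0.022	147	125	54.0	0.017	0.515	109	110	49.8
merC	0.033	0.015	56	216	20.6	0.302	0.001	38	181	17.4
merF	0.108	0.002	25	247	9.2	0.307	0.001	17	202	7.8
merE	0.009	0.192	63	209	23.2	0.132	0.002	38	181	17.4
merG	0.093	0.171	5	267	1.8	0.087	0.488	2	217	0.9
merH	0.129	0.427	1	271	0.4	NA	NA	0	219	0.0
merB	0.066	0.004	42	230	15.4	0.076	0.032	33	186	15.1
merB_multiple	0.126	0.088	5	267	1.8	0.116	0.229	4	215	1.8
merD	0.098	0.001	78	194	28.7	0.289	0.001	45	174	20.5
TRASH	0.141	0.054	5	267	1.8	0.141	0.139	5	214	2.3
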