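sample_id	cp	ee	starch	ndf	adf	ash	crude_fiber	ge	de	me	ne
EP-RSM 1	37.70	11.27	2.95	41.00	24.18	7.49	19.18	21.35	15.78	14.04	10.14
EP-RSM 2	39.75	6.55	4.43	32.34	21.75	6.94	15.04	20.56	15.65	14.30	11.46
SE-RSM 3	39.92	2.58	3.02	37.27	21.50	8.24	13.58	19.47	13.28	12.21	7.98
SE-RSM 4	41.03	1.71	3.12	30.84	20.04	7.22	14.23	19.60	14.07	12.60	9.47
SE-RSM 5	41.83	1.68	2.26	39.83	24.79	9.14	17.86	19.37	11.81	10.88	7.91
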