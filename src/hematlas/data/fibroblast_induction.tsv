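probe_id	gene	avg_untreated_ifn	sd_untreated_ifn	avg_ifn	sd_ifn	fold_ifn	avg_untreated_tsup	sd_untreated_tsup	avg_tsup	sd_tsup	fold_tsup
ILMN_1705247	ACSL5	71.48	18.18	915.69	4.61	12.81	57.07	5.64	410.79	21.92	7.20
ILMN_1756862	APOL3	127.45	50.12	1744.54	88.76	13.69	126.02	3.27	1215.58	198.99	9.65
ILMN_1720048	CCL2	405.52	320.65	566.98	379.69	1.40	146.88	58.76	3739.10	578.67	25.46
ILMN_2098126	CCL5	56.56	5.03	87.02	7.13	1.54	80.04	4.21	1448.07	17.78	18.09
ILMN_1773352	CCL5	55.04	4.49	70.60	14.72	1.28	52.54	0.90	564.89	13.32	10.75
ILMN_1772964	CCL8	79.79	26.74	654.98	396.22	8.21	76.86	23.08	1092.76	27.37	14.22
ILMN_1736567	CD74	105.73	53.25	4540.97	791.32	42.95	59.62	4.58	6697.04	438.61	112.33
ILMN_2379644	CD74	77.73	31.38	1627.96	282.95	20.94	46.04	4.27	3008.86	137.93	65.35
ILMN_1761464	CD74	51.45	1.29	730.79	41.60	14.20	45.18	2.03	518.30	79.50	11.47
ILMN_2047511	CENTA1	187.61	62.18	1916.52	1491.98	10.22	94.46	27.37	664.84	489.58	7.04
ILMN_1791759	CXCL10	51.04	4.63	178.24	64.32	3.49	54.72	1.54	1600.24	844.80	29.24
ILMN_1745356	CXCL9	48.55	4.44	303.32	131.99	6.25	41.91	1.69	5149.88	3359.40	122.89
ILMN_2388547	EPSTI1	124.13	41.46	1691.41	606.22	13.63	165.03	48.22	2084.78	643.31	12.63
ILMN_1701114	GBP1	183.62	52.59	2569.15	182.46	13.99	182.31	43.53	3793.63	414.77	20.81
ILMN_2148785	GBP1	143.83	37.33	1191.59	6.56	8.28	274.42	56.92	5802.20	1534.56	21.14
ILMN_1774077	GBP2	745.66	345.68	17626.86	2385.66	23.64	582.62	90.58	7100.17	300.24	12.19
ILMN_1771385	GBP4	48.49	2.67	903.78	21.36	18.64	57.47	0.85	1439.61	406.66	25.05
ILMN_2114568	GBP5	56.21	4.33	1124.80	148.70	20.01	48.52	1.19	1189.30	25.32	24.51
ILMN_1803945	HCP5	91.78	15.97	892.47	51.92	9.72	71.62	1.81	936.66	97.71	13.08
ILMN_1778401	HLA-B	1305.90	484.58	9930.80	649.29	7.60	1354.92	495.95	15916.89	2069.86	11.75
ILMN_1695311	HLA-DMA	542.10	87.50	7641.55	2580.39	14.10	355.31	31.05	3309.74	1393.47	9.32
ILMN_1761733	HLA-DMB	89.92	32.72	2127.14	1065.96	23.66	66.70	10.93	930.50	471.41	13.95
ILMN_1659075	HLA-DOA	51.01	4.51	897.08	186.07	17.59	51.14	1.29	312.10	118.38	6.10
ILMN_1772218	HLA-DPA1	160.29	7.45	3916.33	585.53	24.43	119.74	3.57	2708.72	724.98	22.62
ILMN_1808405	HLA-DQA1	59.19	9.86	887.82	661.25	15.00	41.27	0.96	870.79	606.77	21.10
ILMN_1689655	HLA-DRA	176.76	126.36	12566.25	3920.68	71.09	93.09	0.69	4449.93	1823.37	47.80
ILMN_2157441	HLA-DRA	138.34	86.70	5530.45	687.54	39.98	62.36	1.05	5817.44	2067.78	93.29
ILMN_1715169	HLA-DRB1	49.64	3.33	302.36	253.61	6.09	51.16	0.40	880.52	833.29	17.21
ILMN_1752592	HLA-DRB4	97.08	25.57	3135.67	1486.29	32.30	59.02	1.21	2467.91	384.34	41.81
ILMN_1697499	HLA-DRB5	73.82	26.82	826.23	777.15	11.19	48.12	0.54	1122.44	1073.92	23.32
ILMN_2066060	HLA-DRB6	56.77	0.82	317.56	109.15	5.59	60.67	1.64	812.22	438.83	13.39
ILMN_2066066	HLA-DRB6	52.33	1.69	192.74	48.32	3.68	48.40	2.49	988.46	215.83	20.42
ILMN_1723912	IFI44L	63.42	5.51	1192.97	174.91	18.81	64.62	10.67	1230.95	168.61	19.05
ILMN_2347798	IFI6	212.00	45.36	2234.49	782.87	10.54	664.54	215.55	12733.61	8737.71	19.16
ILMN_1739428	IFIT2	148.34	6.69	2190.73	666.22	14.77	333.39	47.93	2205.74	1097.87	6.62
ILMN_1701789	IFIT3	309.27	24.42	5293.10	106.34	17.11	248.64	35.15	2465.82	954.09	9.92
ILMN_1664543	IFIT3	61.94	6.84	500.90	52.90	8.09	111.53	4.69	1162.56	556.31	10.42
ILMN_2334296	IL18BP	124.90	13.66	3132.98	608.04	25.08	68.50	2.03	2266.51	1379.17	33.09
ILMN_2368530	IL32	54.42	6.19	149.61	4.61	2.75	109.67	4.68	1873.74	978.51	17.09
ILMN_1656310	INDO	48.99	9.14	523.11	154.06	10.68	45.64	0.65	5685.52	4062.65	124.58
ILMN_1708375	IRF1	498.42	212.95	2664.97	295.19	5.35	277.69	29.54	4185.18	822.05	15.07
ILMN_1662358	MX1	198.75	6.86	10822.34	4316.73	54.45	671.64	353.82	6055.89	2475.95	9.02
ILMN_1701613	RARRES3	291.17	134.16	9431.88	2494.20	32.39	190.98	15.69	4008.61	1773.14	20.99
ILMN_1751079	TAP1	1184.40	16.21	13220.08	1203.62	11.16	824.61	168.64	6181.11	527.53	7.50
ILMN_1678841	UBD	49.97	2.18	76.70	15.87	1.53	52.95	1.42	1077.09	664.73	20.34
ILMN_1727271	WARS	1219.84	167.93	18566.63	8233.61	15.22	364.88	11.13	7669.97	593.84	21.02
ILMN_2337655	WARS	1267.64	209.92	13887.52	4384.17	10.96	508.79	30.61	11333.68	2227.47	22.28
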