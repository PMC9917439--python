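# Underreplicated domains called in w1118 L3 salivary glands (euchromatic arms),
# with mean normalized copy number <CN> per genotype, percent recovery and mean
# per-bin p-value per mutant. Coordinates 1-based inclusive, dm6.
domain	arm	start	end	cyto_band	length_bp	cn_w1118	cn_SuUR_ES	recovery_SuUR_ES	p_SuUR_ES	cn_mod_mdg4_m9	recovery_mod_mdg4_m9	p_mod_mdg4_m9
1	X	2950001	3140000	3C3-C7	190000	0.51	0.93	86	7.3E-05	0.58	14	1.1E-02
2	X	4710001	4900000	4C15-D5	190000	0.56	0.96	92	3.9E-04	0.81	57	6.9E-05
3	X	4965001	5070000	4E1-E2	105000	0.72	0.86	50	5.6E-04	0.80	28	1.4E-02
4	X	6415001	6525000	6A1-B1	110000	0.71	0.90	65	1.4E-03	0.80	29	7.3E-03
5	X	7335001	7560000	7B1-B4	225000	0.65	0.98	95	1.2E-03	0.79	40	2.8E-03
6	X	7750001	7865000	7B7-C1	115000	0.64	0.94	84	3.0E-09	0.84	55	5.2E-07
7	X	8880001	9005000	8B5-C2	125000	0.73	0.86	50	5.5E-03	0.76	9	4.6E-03
8	X	9405001	9555000	8D12-E7	150000	0.72	0.91	67	3.6E-04	0.85	47	3.6E-03
9	X	11170001	11325000	10A10-B3	155000	0.67	0.84	53	3.2E-03	0.78	35	2.6E-03
10	X	12040001	12430000	11A2-A10	390000	0.38	0.97	94	1.4E-08	0.42	6	6.8E-03
11	X	13950001	14100000	12D1-E1	150000	0.69	0.72	10	1.0E-02	0.73	14	1.4E-02
12	X	14290001	14565000	12E7-F1	275000	0.51	0.94	87	4.1E-04	0.69	36	8.1E-04
13	X	17925001	18030000	16F3-F5	105000	0.67	0.99	98	1.7E-15	0.90	68	3.4E-05
14	X	20000001	20105000	19A4-B1	105000	0.79	1.12	157	1.4E-13	0.82	12	6.1E-03
15	X	20525001	21020000	19D2-E7	495000	0.50	0.97	93	1.3E-07	0.51	2	4.9E-03
16	X	21630001	22450000	20A5-C1	820000	0.04	0.32	29	1.8E-03	0.06	2	6.4E-03
17	X	22550001	22995000	20C2-F3	445000	0.48	0.81	64	7.8E-05	0.74	51	3.5E-04
18	2L	3920001	4025000	24D1-D4	105000	0.63	0.93	81	7.9E-07	0.80	46	5.9E-05
19	2L	4585001	4790000	25A2-A5	205000	0.66	0.99	98	1.9E-08	0.78	36	1.3E-03
20	2L	5400001	5510000	25E1-E4	110000	0.82	0.99	95	4.0E-08	0.90	45	8.3E-03
21	2L	6155001	6320000	26B9-C2	165000	0.74	1.08	130	7.3E-14	0.88	54	4.7E-04
22	2L	9030001	9150000	29F8-30A2	120000	0.76	0.98	93	1.5E-04	0.95	79	3.3E-03
23	2L	11535001	11795000	32F2-33A1	260000	0.44	0.90	83	2.9E-04	0.57	24	1.5E-03
24	2L	12215001	12340000	33D3-E1	125000	0.58	0.86	66	3.6E-11	0.75	40	1.1E-04
25	2L	12765001	12970000	33F5-34A3	205000	0.55	0.91	79	8.8E-04	0.73	40	7.0E-05
26	2L	14685001	15010000	35B4-B8	325000	0.41	0.88	80	5.7E-04	0.54	23	7.2E-04
27	2L	15295001	15735000	35D1-D4	440000	0.49	0.76	53	2.3E-05	0.54	9	4.0E-03
28	2L	15770001	15900000	35D4-D6	130000	0.54	0.87	71	4.5E-08	0.68	31	6.7E-04
29	2L	15925001	16240000	35D6-F1	315000	0.29	0.90	87	6.7E-07	0.38	12	1.4E-05
30	2L	16925001	17375000	36B4-C7	450000	0.23	0.89	85	1.4E-04	0.26	4	4.3E-03
31	2L	17515001	18100000	36C10-E4	585000	0.34	0.87	80	5.0E-06	0.36	2	3.7E-03
32	2L	18160001	18300000	36E6-F2	140000	0.67	0.99	97	3.3E-06	0.90	69	3.1E-06
33	2L	20110001	20290000	38C1-C4	180000	0.48	0.69	41	8.9E-04	0.46	-5	1.8E-03
34	2L	20485001	20620000	38C8-D1	135000	0.77	0.98	93	1.0E-06	0.99	97	2.1E-05
35	2L	21400001	21550000	39D3-E2	150000	0.10	0.15	5	3.2E-03	0.14	3	4.4E-03
36	2L	21805001	22125000	40A4-E4	320000	0.53	0.94	87	6.9E-05	0.54	1	9.5E-03
37	2R	4875001	5050000	41C4-D1	175000	0.35	0.86	78	2.3E-10	0.34	-1	4.0E-03
38	2R	5410001	5535000	41F1-F3	125000	0.58	0.79	50	1.1E-03	0.52	-13	2.2E-03
39	2R	6290001	6505000	42A14-B1	215000	0.13	0.50	42	9.3E-04	0.14	1	2.7E-03
40	2R	13620001	13760000	50B6-C3	140000	0.63	0.95	88	4.1E-18	0.78	41	1.3E-05
41	2R	20355001	20540000	56F17-57A5	185000	0.56	0.92	83	2.0E-06	0.71	35	8.2E-04
42	2R	21830001	21945000	58A2-A4	115000	0.72	0.95	83	1.1E-05	0.71	-3	2.2E-02
43	2R	23145001	23320000	59D1-D6	175000	0.62	1.04	110	1.3E-22	0.67	13	7.7E-03
44	3L	4840001	5100000	64C1-C5	260000	0.38	0.92	87	3.5E-08	0.40	3	6.6E-03
45	3L	5385001	5510000	64C15-D3	125000	0.51	0.88	76	1.9E-22	0.73	45	6.0E-09
46	3L	6290001	6485000	65A11-B3	195000	0.52	0.89	77	4.9E-05	0.71	38	1.2E-04
47	3L	9180001	9300000	67A1-A7	120000	0.67	0.97	90	6.5E-09	0.73	20	1.0E-02
48	3L	10000001	10195000	67D3-D10	195000	0.62	0.97	93	4.4E-13	0.79	44	5.7E-06
49	3L	13085001	13220000	70A1-A2	135000	0.66	1.01	104	3.6E-09	0.89	66	2.9E-06
50	3L	13550001	13855000	70B6-C4	305000	0.26	0.95	94	1.8E-06	0.39	18	7.3E-04
51	3L	15175001	15500000	71B7-D3	325000	0.39	0.94	89	5.6E-04	0.46	10	3.7E-03
52	3L	17115001	17240000	73F1-74A1	125000	0.71	1.02	106	4.3E-05	0.84	45	2.7E-03
53	3L	18175001	18525000	75B11-75D2	350000	0.45	0.87	76	6.8E-05	0.47	4	4.6E-03
54	3L	20555001	20695000	77D1-77E3	140000	0.60	1.02	106	2.2E-22	0.84	61	3.6E-11
55	3R	6060001	6310000	83D2-E4	250000	0.70	0.92	72	7.6E-04	0.63	-22	1.0E-02
56	3R	6495001	6635000	83F1-84A1	140000	0.53	0.96	91	7.8E-08	0.71	39	2.2E-04
57	3R	6915001	7055000	84B1-B2	140000	0.64	0.93	80	3.9E-04	0.82	49	1.9E-05
58	3R	7550001	7785000	84D9-84E2	235000	0.44	0.80	65	8.0E-06	0.51	12	4.2E-03
59	3R	10450001	10660000	86B6-C4	210000	0.55	0.98	97	8.1E-11	0.66	25	7.6E-04
60	3R	10910001	11140000	88C15-86D4	230000	0.45	0.94	89	2.3E-10	0.46	2	2.3E-03
61	3R	12050001	12165000	87A5-B1	115000	0.63	0.96	88	9.9E-24	0.81	49	5.9E-09
62	3R	12745001	12935000	87C8-D4	190000	0.67	0.89	68	7.5E-05	0.60	-21	1.1E-02
63	3R	14935001	15055000	88D8-D10	120000	0.70	0.88	61	7.6E-06	0.84	47	1.0E-04
64	3R	16670001	16970000	89D6-E5	300000	0.40	0.92	87	2.7E-09	0.47	10	3.2E-03
65	3R	17160001	17355000	89F1-90A2	195000	0.62	0.94	84	1.0E-03	0.86	64	2.8E-04
66	3R	20085001	20290000	92C4-E1	205000	0.61	0.81	53	1.5E-03	0.71	26	3.6E-03
67	3R	20340001	20525000	92E4-E12	185000	0.58	0.96	91	5.0E-05	0.79	50	7.2E-04
68	3R	22110001	22295000	94A2-A4	185000	0.61	0.93	83	3.4E-11	0.76	39	3.0E-04
69	3R	28005001	28295000	98B7-C3	290000	0.40	0.91	85	2.5E-05	0.60	32	6.9E-04
70	3R	28370001	28480000	98C5-D2	110000	0.73	0.98	94	1.2E-09	0.91	66	4.3E-07
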