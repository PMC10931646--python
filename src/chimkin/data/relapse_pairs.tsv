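patient_id	sample_t1	sample_t2	str_ct1	str_ct2	allo_ct1	allo_ct2	days_hct_to_t1	interval_days	relapsed	relapse_diagnosed_days_after_t2
1	p1_post1	p1_post2	0.8	79.9	0.48	80.40	23	11	yes	0
2	p2_post1	p2_post2	0.8	22.1	0.73	25.45	28	3	yes	42
3	p3_post1	p3_post2	0.8	3.2	0.36	3.58	77	28	no	0
3	p3_post3	p3_post4	0.8	0.8	0.6	0.36	143	33	no	0
4	p4_post1	p4_post2	0.8	0.8	1.16	0.55	124	28	no	0
4	p4_post2	p4_post3	0.8	3.8	0.55	3.52	142	28	yes	0
5	p5_post1	p5_post2	0.8	0.8	0.74	0.72	989	36	no	0
5	p5_post2	p5_post3	0.8	42.1	0.72	36.76	1025	26	no	0
6	p6_post1	p6_post2	0.8	3.1	0.36	2.66	453	10	no	0
7	p7_post1	p7_post2	0.8	0.8	0.36	0.36	37	34	no	0
7	p7_post2	p7_post3	0.8	8.9	0.36	6.76	71	10	yes	0
8	p8_post1	p8_post2	0.8	6.6	0.62	4.28	574	28	yes	4
9	p9_post1	p9_post2	0.8	5.8	0.36	4.55	106	26	no	0
10	p10_post1	p10_post2	0.8	42.3	1.04	41.56	51	27	yes	0
11	p11_post1	p11_post2	0.8	59.1	0.98	62.16	223	20	yes	0
12	p12_post1	p12_post2	0.8	16.5	0.36	16.21	52	27	yes	0
13	p13_post1	p13_post2	0.8	2.5	0.36	2.17	15	14	no	0
13	p13_post3	p13_post4	0.8	0.8	0.36	0.36	152	25	no	0
14	p14_post1	p14_post2	0.8	3.4	0.76	3.2	16	13	no	0
15	p15_post1	p15_post2	0.8	9.9	0.44	9.48	85	27	yes	0
16	p16_post1	p16_post2	0.8	1.2	0.65	1.17	101	28	no	0
16	p16_post3	p16_post4	0.8	0.8	0.36	0.54	157	28	no	0
17	p17_post1	p17_post2	0.8	0.8	0.41	0.67	29	34	no	0
17	p17_post2	p17_post3	0.8	80.2	0.67	80.41	63	28	yes	0
18	p18_post1	p18_post2	0.8	4.7	0.36	2.59	160	28	no	0
19	p19_post1	p19_post2	0.8	17.1	0.41	18.62	51	28	yes	0
20	p20_post1	p20_post2	0.8	1.4	0.36	0.99	48	28	no	0
21	p21_post1	p21_post2	0.8	0.8	0.36	0.78	101	40	no	0
22	p22_post1	p22_post2	0.8	0.8	0.36	0.57	1656	30	no	0
23	p23_post1	p23_post2	0.8	0.8	0.36	0.54	91	34	no	0
24	p24_post1	p24_post2	0.8	0.8	0.36	0.36	238	27	no	0
25	p25_post1	p25_post2	0.8	0.8	0.36	0.36	621	28	no	0
26	p26_post1	p26_post2	0.8	0.8	1.13	2.7	305	31	no	0
27	p27_post1	p27_post2	0.8	0.8	0.95	0.83	70	35	yes	0
28	p28_post1	p28_post2	0.8	0.8	0.47	0.44	57	48	no	0
29	p29_post1	p29_post2	0.8	0.8	0.36	0.36	1205	20	no	0
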