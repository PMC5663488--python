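# DRB1 allele/serogroup carrier counts, 360 cases vs 1026 controls, with the
# published association statistics (pub_* columns) for regression checking.
# pub_pc empty = not reported; "NS" = reported not significant.
unit	case_carriers	case_total	control_carriers	control_total	pub_p	pub_or	pub_pc	pub_ci_low	pub_ci_high
DRB1*01:01	26	360	110	1026	0.0634	0.65	NS	0.42	1.01
DRB1*03:01	1	360	3	1026	1.0000	0.95	NS	0.10	9.16
DRB1*04:01	22	360	22	1026	0.0006	2.97	0.0193	1.62	5.43
DRB1*04:03	15	360	47	1026	0.8823	0.91	NS	0.50	1.64
DRB1*04:04	0	360	4	1026	0.5780	0.32	NS	0.02	5.87
DRB1*04:05	185	360	243	1026	1.89e-21	3.41	5.68e-20	2.65	4.38
DRB1*04:06	15	360	76	1026	0.0351	0.54	NS	0.31	0.96
DRB1*04:07	5	360	15	1026	1.0000	0.95	NS	0.34	2.63
DRB1*04:10	12	360	32	1026	0.8616	1.07	NS	0.55	2.10
DRB1*07:01	2	360	9	1026	0.7382	0.63	NS	0.14	2.94
DRB1*08:02	35	360	72	1026	0.1080	1.43	NS	0.93	2.18
DRB1*08:03	58	360	153	1026	0.6091	1.10	NS	0.79	1.52
DRB1*08:09	0	360	2	1026	1.0000	0.57	NS	0.03	11.87
DRB1*09:01	77	360	280	1026	0.0298	0.72	0.8949	0.54	0.97
DRB1*10:01	5	360	5	1026	0.1381	2.88	NS	0.83	9.99
DRB1*11:01	8	360	41	1026	0.1361	0.55	NS	0.25	1.18
DRB1*12:01	25	360	75	1026	0.9059	0.95	NS	0.59	1.51
DRB1*12:02	11	360	37	1026	0.7384	0.84	NS	0.43	1.67
DRB1*13:01	2	360	8	1026	1.0000	0.71	NS	0.15	3.36
DRB1*13:02	30	360	163	1026	0.0003	0.48	0.0080	0.32	0.72
DRB1*14:02	1	360	0	1026	0.2597	8.57	NS	0.35	210.76
DRB1*14:03	5	360	44	1026	0.0078	0.31	0.2337	0.12	0.80
DRB1*14:04	0	360	4	1026	0.5780	0.32	NS	0.02	5.87
DRB1*14:05	13	360	40	1026	0.8744	0.92	NS	0.49	1.75
DRB1*14:06	5	360	29	1026	0.1655	0.48	NS	0.19	1.26
DRB1*14:07	1	360	2	1026	1.0000	1.43	NS	0.13	15.78
DRB1*14:54	20	360	58	1026	1.0000	0.98	NS	0.58	1.66
DRB1*15:01	41	360	139	1026	0.3171	0.82	NS	0.57	1.19
DRB1*15:02	62	360	224	1026	0.0692	0.74	NS	0.55	1.02
DRB1*16:02	5	360	18	1026	0.8119	0.79	NS	0.29	2.14
DR4	238	360	406	1026	3.84e-18	2.98		2.32	3.83
DR6	74	360	332	1026	2.10e-5	0.54		0.41	0.72
DR8	92	360	220	1026	0.1234	1.26		0.95	1.66
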