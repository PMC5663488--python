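# DRB1-DQB1 haplotype carrier and diplotype counts, 360 cases vs the 413
# DQB1-typed controls, with the published statistics.
unit	case_carriers	case_total	control_carriers	control_total	pub_p	pub_or	pub_pc	pub_ci_low	pub_ci_high
DRB1*04:01-DQB1*03:01	22	360	6	413	0.0007	4.42		1.77	11.01
DRB1*04:05-DQB1*04:01	182	360	79	413	1.99e-20	4.32		3.14	5.96
DRB1*08:02-DQB1*03:02	21	360	21	413	0.7508	1.16		0.62	2.15
DRB1*08:02-DQB1*04:02	13	360	16	413	1.0000	0.93		0.44	1.96
DRB1*08:03-DQB1*03:01	3	360	2	413	0.6682	1.73		0.29	10.39
DRB1*08:03-DQB1*06:01	57	360	57	413	0.4768	1.17		0.79	1.75
DRB1*13:02-DQB1*06:04	31	360	49	413	0.1559	0.70		0.44	1.12
DRB1*04:05-DQB1*04:01/not	165	360	75	413	1.17e-16	3.81		2.76	5.28
DRB1*04:05-DQB1*04:01/DRB1*04:01-DQB1*03:01	4	360	1	413	0.1898	4.63		0.52	41.61
DRB1*04:05-DQB1*04:01/DRB1*04:05-DQB1*04:01	17	360	4	413	0.0015	5.07		1.69	15.20
DRB1*04:05-DQB1*04:01/DRB1*08:02-DQB1*03:02	10	360	0	413	0.0004	24.77		1.45	424.31
DRB1*04:05-DQB1*04:01/DRB1*08:02-DQB1*04:02	7	360	3	413	0.2017	2.71		0.70	10.56
DRB1*04:05-DQB1*04:01/DRB1*08:03-DQB1*03:01	1	360	0	413	0.4657	3.45		0.14	84.97
DRB1*04:05-DQB1*04:01/DRB1*08:03-DQB1*06:01	26	360	3	413	1.18e-6	10.64		3.19	35.46
DRB1*04:05-DQB1*04:01/DRB1*13:02-DQB1*06:04	8	360	8	413	0.8052	1.15		0.43	3.10
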