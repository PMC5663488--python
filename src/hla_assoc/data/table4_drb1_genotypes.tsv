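# DRB1 genotype-class counts, 360 cases vs 1026 controls, with the published
# statistics.  "X/not" = heterozygous carriers of X (one copy only);
# serogroup pairs (DR4/DR8) cross the group memberships.
unit	case_carriers	case_total	control_carriers	control_total	pub_p	pub_or	pub_pc	pub_ci_low	pub_ci_high
DRB1*04:05/not	167	360	224	1026	5.72e-18	3.10		2.40	4.00
DRB1*13:02/not	30	360	154	1026	0.0011	0.51		0.34	0.78
DRB1*04:01/not	22	360	21	1026	0.0003	3.11		1.69	5.74
DRB1*04:01/DRB1*04:05	4	360	1	1026	0.0178	11.52		1.28	103.39
DRB1*04:05/DRB1*04:05	18	360	19	1026	0.0035	2.79		1.45	5.38
DRB1*04:05/DRB1*08:02	18	360	8	1026	3.78e-6	6.70		2.89	15.54
DRB1*04:05/DRB1*08:03	27	360	18	1026	9.80e-7	4.54		2.47	8.35
DRB1*04:05/DRB1*13:02	8	360	25	1026	1.0000	0.91		0.41	2.04
DRB1*13:02/DRB1*13:02	0	360	9	1026	0.1225	0.15		0.01	2.56
DR4/DR4	34	360	57	1026	0.0132	1.77		1.14	2.76
DR8/DR8	5	360	16	1026	1.0000	0.89		0.32	2.44
DR6/DR6	3	360	25	1026	0.0796	0.34		0.10	1.12
DR4/DR8	54	360	49	1026	3.12e-9	3.52		2.34	5.29
DR4/DR6	32	360	90	1026	0.9144	1.01		0.66	1.55
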