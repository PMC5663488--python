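# Presumed DQA1 allele carried on each DRB1-DQB1 haplotype (conserved
# Japanese haplotype structure).  These assignments are population-level
# presumptions, not typed data; extend with caution.
drb1	dqb1	dqa1
DRB1*04:05	DQB1*04:01	DQA1*03:03
DRB1*08:02	DQB1*03:02	DQA1*03:01
DRB1*08:03	DQB1*06:01	DQA1*01:03
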