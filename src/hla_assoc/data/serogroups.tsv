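# DRB1 serological groups used by the bundled analyses (Japanese panel).
group	allele
DR4	DRB1*04:01
DR4	DRB1*04:03
DR4	DRB1*04:04
DR4	DRB1*04:05
DR4	DRB1*04:06
DR4	DRB1*04:07
DR4	DRB1*04:10
DR6	DRB1*13:01
DR6	DRB1*13:02
DR6	DRB1*14:03
DR6	DRB1*14:04
DR6	DRB1*14:05
DR6	DRB1*14:06
DR6	DRB1*14:07
DR6	DRB1*14:29
DR6	DRB1*14:54
DR8	DRB1*08:02
DR8	DRB1*08:03
DR8	DRB1*08:09
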