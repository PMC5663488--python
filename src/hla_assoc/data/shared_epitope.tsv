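# Shared-epitope DRB1 alleles with their DRbeta 70-74 motif.
# Motifs curated from the rheumatoid-arthritis shared-epitope literature;
# verify against a current IMGT/HLA alignment before scientific use.
allele	motif_70_74
DRB1*01:01	QRRAA
DRB1*04:01	QKRAA
DRB1*04:04	QRRAA
DRB1*04:05	QRRAA
DRB1*04:10	QRRAA
DRB1*10:01	RRRAA
DRB1*14:02	QRRAA
DRB1*14:06	QRRAA
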