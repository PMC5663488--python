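# Partial curated DRbeta residue table (mature-protein numbering: position 1
# is the first residue after the signal peptide).  Covers the 70-74 motif for
# the shared-epitope alleles and DRB1*13:01/*13:02, and the polymorphic
# positions 11/13/33/57/96 for DRB1*04:05.  This file is a convenience
# default for demonstrations only; residue scans for publication should use a
# table derived from a current IMGT/HLA protein alignment.
allele	position	residue
DRB1*01:01	70	Q
DRB1*01:01	71	R
DRB1*01:01	72	R
DRB1*01:01	73	A
DRB1*01:01	74	A
DRB1*04:01	70	Q
DRB1*04:01	71	K
DRB1*04:01	72	R
DRB1*04:01	73	A
DRB1*04:01	74	A
DRB1*04:04	70	Q
DRB1*04:04	71	R
DRB1*04:04	72	R
DRB1*04:04	73	A
DRB1*04:04	74	A
DRB1*04:05	70	Q
DRB1*04:05	71	R
DRB1*04:05	72	R
DRB1*04:05	73	A
DRB1*04:05	74	A
DRB1*04:05	11	V
DRB1*04:05	13	H
DRB1*04:05	33	H
DRB1*04:05	57	S
DRB1*04:05	96	Y
DRB1*04:10	70	Q
DRB1*04:10	71	R
DRB1*04:10	72	R
DRB1*04:10	73	A
DRB1*04:10	74	A
DRB1*10:01	70	R
DRB1*10:01	71	R
DRB1*10:01	72	R
DRB1*10:01	73	A
DRB1*10:01	74	A
DRB1*13:01	70	D
DRB1*13:01	71	E
DRB1*13:01	72	R
DRB1*13:01	73	A
DRB1*13:01	74	A
DRB1*13:02	70	D
DRB1*13:02	71	E
DRB1*13:02	72	R
DRB1*13:02	73	A
DRB1*13:02	74	A
DRB1*14:02	70	Q
DRB1*14:02	71	R
DRB1*14:02	72	R
DRB1*14:02	73	A
DRB1*14:02	74	A
DRB1*14:06	70	Q
DRB1*14:06	71	R
DRB1*14:06	72	R
DRB1*14:06	73	A
DRB1*14:06	74	A
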