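#name	recognition	cut_offset_top	cut_offset_bottom
AvaII	GGWCC	1	4
MspI	CCGG	1	3
EcoRI	GAATTC	1	5
PstI	CTGCAG	5	1
SbfI	CCTGCAGG	2	6
MluCI	AATT	0	4
NlaIII	CATG	4	0
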