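locus	strand	amplicon	clones	sequenced
K(I)	rev	LTR	1	8
K(I)	rev	pro	2	9
K(I)	rev	env-1	6	8
K(I)	rev	env-3	5	7
K106	rev	pro	1	9
K106	rev	env-2	3	9
K106	rev	env-3	1	7
K50F	rev	env-1	2	8
K50F	rev	env-2	5	9
Fragment_11q12.3	rev	env-2	1	9
Fragment_11q12.3	rev	env-3	1	7
K118	fwd	env-1	10	10
K118	fwd	env-2	10	10
K118	fwd	env-3	7	7
Fragment_7q34	rev	pro	6	9
SoloLTR	rev	LTR	7	8
SoloLTR	fwd	LTR	10	10
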