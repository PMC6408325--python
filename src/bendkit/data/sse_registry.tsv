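# Tubulin secondary-structure element registry (structure-based canonical numbering).
# Ranges are inclusive and provisional (+/- 2 residues); users may substitute their own file.
# columns: subunit	name	kind	start	end
alpha	S1	strand	3	9
alpha	H1	helix	10	27
alpha	H1-S2	loop	38	46
alpha	S2	strand	47	52
alpha	H2	helix	57	63
alpha	S3	strand	67	72
alpha	H3	helix	76	88
alpha	S4	strand	95	100
alpha	H4	helix	105	112
alpha	S5	strand	118	123
alpha	H5	helix	129	135
alpha	S6	strand	163	168
alpha	H6	helix	170	180
alpha	S7	strand	206	212
alpha	H7	helix	224	243
alpha	T7	loop	244	251
alpha	H8	helix	252	260
alpha	H9	helix	285	295
alpha	S8	strand	312	316
alpha	H10	helix	320	330
alpha	H10-S9	loop	331	349
alpha	S9	strand	350	356
alpha	S10	strand	365	371
alpha	H11	helix	385	395
alpha	H12	helix	418	432
beta	S1	strand	3	9
beta	H1	helix	10	27
beta	H1-S2	loop	38	46
beta	S2	strand	47	52
beta	H2	helix	57	63
beta	S3	strand	67	72
beta	H3	helix	76	88
beta	S4	strand	95	100
beta	H4	helix	105	112
beta	S5	strand	118	123
beta	H5	helix	129	135
beta	S6	strand	163	168
beta	H6	helix	170	180
beta	S7	strand	206	212
beta	H7	helix	224	243
beta	T7	loop	244	251
beta	H8	helix	252	260
beta	H9	helix	285	295
beta	S8	strand	312	316
beta	H10	helix	320	330
beta	H10-S9	loop	331	349
beta	S9	strand	350	356
beta	S10	strand	365	371
beta	H11	helix	385	395
beta	H12	helix	418	432
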