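# Human 5' (donor) splice-site base frequencies (percent), consensus MAG|GTRAGT.
# Positions -3..-1 exonic, +1..+6 intronic; the GT at +1/+2 is near-invariant.
pos	A	C	G	T
-3	33	37	18	12
-2	61	13	12	14
-1	10	3	79	8
1	0.1	0.1	99.7	0.1
2	0.1	0.1	0.1	99.7
3	40	3	55	2
4	71	8	12	9
5	6	6	84	4
6	15	18	21	46
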