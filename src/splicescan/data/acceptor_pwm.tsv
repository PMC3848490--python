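# Human 3' (acceptor) splice-site base frequencies (percent).
# Positions -14..-1 intronic (polypyrimidine tract then the invariant AG at
# -2/-1), +1 the first exonic base.
pos	A	C	G	T
-14	10	31	10	49
-13	9	33	9	49
-12	9	33	10	48
-11	8	35	9	48
-10	9	37	9	45
-9	9	38	9	44
-8	9	41	8	42
-7	8	44	8	40
-6	7	42	8	43
-5	8	40	7	45
-4	24	30	21	25
-3	4	74	1	21
-2	99.7	0.1	0.1	0.1
-1	0.1	0.1	99.7	0.1
1	25	15	48	12
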