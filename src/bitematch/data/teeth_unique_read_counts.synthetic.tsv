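# SYNTHETIC stand-in: per-teeth-sample unique-read counts used only for the
# "fewest unique reads" tie-break in best-match selection. The study's true
# per-sample counts were published only as bar charts; these values are
# invented, but their ordering encodes the documented tie-break outcomes:
# 16S: T10 < T13 and T10 < T16 (tie at B1 resolved to T10);
#      T6 < T5 (tie at B6 resolved to the corresponding sample);
# ITS: T10 < T8 (tie at B8 resolved to T10).
sample	16S	ITS	rpoB
T1	55	50	30
T3	48	46	34
T4	60	52	28
T5	62	44	33
T6	40	38	25
T7	52	47	29
T8	45	55	27
T9	58	41	36
T10	30	35	31
T12	120	110	140
T13	150	125	120
T14	90	85	100
T15	130	95	95
T16	140	160	110
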