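K	GEV
3	0.5450
4	0.5828
5	0.6094
6	0.6275
7	0.6418
8	0.6519
9	0.6614
10	0.6678
11	0.6738
12	0.6794
13	0.6841
14	0.6884
15	0.6925
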