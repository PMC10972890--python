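K	GEV
3	0.5403
4	0.5723
5	0.5968
6	0.6123
7	0.6251
8	0.6345
9	0.6432
10	0.6511
11	0.6567
12	0.6618
13	0.6670
14	0.6714
15	0.6753
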