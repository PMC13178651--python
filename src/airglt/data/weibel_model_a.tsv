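# Weibel (1963) "model A" regularized symmetric dichotomous airway tree:
# mean airway diameter per generation, mm, referenced to total lung capacity
# (lung volume ~4800 mL). Generation 0 is the trachea; generation z holds
# 2^z parallel branches. Override with a file of the same layout via
# build_weibel_tree(diameter_table=...) or the --diameters CLI flag.
# table_version: weibel-1963-model-A/v1
generation	diameter_tlc_mm
0	18.0
1	12.2
2	8.3
3	5.6
4	4.5
5	3.5
6	2.8
7	2.3
8	1.86
9	1.54
10	1.30
11	1.09
12	0.95
13	0.82
14	0.74
15	0.66
16	0.60
17	0.54
18	0.50
19	0.47
20	0.45
21	0.43
22	0.41
23	0.41
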