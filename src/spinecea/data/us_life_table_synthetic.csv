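age,qx
18,0.000800
19,0.000849
20,0.000900
21,0.000919
22,0.000939
23,0.000959
24,0.000979
25,0.001000
26,0.001019
27,0.001039
28,0.001059
29,0.001079
30,0.001100
31,0.001154
32,0.001211
33,0.001271
34,0.001334
35,0.001400
36,0.001488
37,0.001582
38,0.001682
39,0.001787
40,0.001900
41,0.002082
42,0.002281
43,0.002499
44,0.002738
45,0.003000
46,0.003253
47,0.003528
48,0.003826
49,0.004149
50,0.004500
51,0.004843
52,0.005213
53,0.005611
54,0.006039
55,0.006500
56,0.006983
57,0.007501
58,0.008059
59,0.008657
60,0.009300
61,0.010064
62,0.010890
63,0.011785
64,0.012753
65,0.013800
66,0.014980
67,0.016261
68,0.017652
69,0.019161
70,0.020800
71,0.022742
72,0.024865
73,0.027187
74,0.029725
75,0.032500
76,0.035812
77,0.039462
78,0.043484
79,0.047916
80,0.052800
81,0.058625
82,0.065093
83,0.072274
84,0.080247
85,0.089100
86,0.098578
87,0.109063
88,0.120664
89,0.133500
90,0.147700
91,0.160786
92,0.175032
93,0.190540
94,0.207422
95,0.225800
96,0.241835
97,0.259009
98,0.277402
99,0.297102
100,0.318200
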