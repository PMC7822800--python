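energy_keV,relative_fluence
23,4.5231843e-11
24,6.4221816e-10
25,6.0159051e-09
26,4.0187743e-08
27,2.0350333e-07
28,8.1929423e-07
29,2.7226561e-06
30,7.7145822e-06
31,1.9094235e-05
32,4.2140994e-05
33,8.4426397e-05
34,0.00015542756
35,0.00026659233
36,0.00042930124
37,0.00065569859
38,0.00095478481
39,0.0013356706
40,0.0018007805
41,0.0023546192
42,0.0029908385
43,0.0037091118
44,0.0044977458
45,0.0053493994
46,0.0062536316
47,0.0071931355
48,0.0081638522
49,0.0091440804
50,0.010127907
51,0.011107858
52,0.012059203
53,0.012988466
54,0.013884137
55,0.01472944
56,0.015533163
57,0.01628639
58,0.016975756
59,0.017613635
60,0.018196554
61,0.018707722
62,0.01916495
63,0.019568337
64,0.019903992
65,0.020183723
66,0.020413229
67,0.02058929
68,0.020705636
69,0.020777685
70,0.020807242
71,0.020787278
72,0.020722503
73,0.020622189
74,0.020488214
75,0.020313397
76,0.020104744
77,0.019869113
78,0.019608192
79,0.019317382
80,0.018999723
81,0.018662608
82,0.018307432
83,0.017933831
84,0.017537159
85,0.017127243
86,0.016705178
87,0.016272002
88,0.015824275
89,0.015364792
90,0.014897816
91,0.014424127
92,0.013944457
93,0.013455319
94,0.01296059
95,0.012462504
96,0.011961586
97,0.011458334
98,0.010950695
99,0.010440466
100,0.0099297516
101,0.0094188922
102,0.0089082072
103,0.0083974148
104,0.0078854222
105,0.0073748747
106,0.0068659812
107,0.0063589348
108,0.0058539141
109,0.0053503019
110,0.0048485263
111,0.0043495628
112,0.0038535172
113,0.0033604858
114,0.0028705556
115,0.0023835139
116,0.0018996097
117,0.0014192686
118,0.00094253097
119,0.00046943156
120,0
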