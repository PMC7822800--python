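energy_keV,relative_fluence
9,6.37097e-11
10,2.2113554e-08
11,1.0697412e-06
12,1.536416e-05
13,0.00010103385
14,0.00039496144
15,0.0010797977
16,0.0022960509
17,0.0040736788
18,0.0063275512
19,0.0088988957
20,0.011606858
21,0.014287204
22,0.016812325
23,0.019096221
24,0.021090573
25,0.022766201
26,0.024130194
27,0.025202976
28,0.026004969
29,0.026554533
30,0.026896756
31,0.027049738
32,0.027040905
33,0.026904806
34,0.02664428
35,0.026301191
36,0.025870488
37,0.025386944
38,0.024845119
39,0.024272646
40,0.023661302
41,0.023036295
42,0.022386474
43,0.021732425
44,0.021068537
45,0.020403534
46,0.019740895
47,0.019077534
48,0.01842364
49,0.01777325
50,0.017132178
51,0.016502948
52,0.015879419
53,0.015269313
54,0.0146712
55,0.014082206
56,0.013506915
57,0.012943965
58,0.012391135
59,0.011851661
60,0.011324857
61,0.010807889
62,0.010303596
63,0.0098115674
64,0.0093296604
65,0.0088590129
66,0.0083997989
67,0.0079512016
68,0.0075122107
69,0.0070837836
70,0.0066655569
71,0.0062565752
72,0.0058567724
73,0.0054663416
74,0.005084963
75,0.0047118863
76,0.0043471308
77,0.0039906709
78,0.0036422288
79,0.0033013293
80,0.0029678089
81,0.0026416304
82,0.0023225538
83,0.0020103152
84,0.0017046013
85,0.0014053929
86,0.0011124834
87,0.00082567509
88,0.00054475273
89,0.00026957727
90,0
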