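energy_keV,relative_fluence
9,9.1087695e-11
10,3.1486845e-08
11,1.5167464e-06
12,2.16896e-05
13,0.00014199085
14,0.00055250787
15,0.0015033259
16,0.003180921
17,0.0056149919
18,0.0086759263
19,0.012135489
20,0.015739682
21,0.019262097
22,0.022530428
23,0.025431959
24,0.027906901
25,0.029922582
26,0.03149509
27,0.032657961
28,0.033444389
29,0.033884573
30,0.034042228
31,0.033945717
32,0.033634592
33,0.033156301
34,0.032518297
35,0.031775333
36,0.030924246
37,0.030009436
38,0.029026659
39,0.028010314
40,0.026952511
41,0.025883553
42,0.024792015
43,0.023701915
44,0.022607849
45,0.021519998
46,0.020442535
47,0.019372736
48,0.018321379
49,0.017282701
50,0.016262673
51,0.015263701
52,0.014280152
53,0.013319136
54,0.012379197
55,0.011457853
56,0.010558802
57,0.0096806846
58,0.0088216877
59,0.0079839817
60,0.0071667262
61,0.006367878
62,0.0055889487
63,0.0048292758
64,0.0040874559
65,0.0033637574
66,0.0026578286
67,0.0019689538
68,0.0012965355
69,0.00064040591
70,0
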