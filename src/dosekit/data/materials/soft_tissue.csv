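energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,41.343956,41.079582,0.99355543,0.005227544,0.0012170299
5.2773558,35.170884,34.911752,0.99257023,0.0061386063,0.0012911654
5.5700968,29.924417,29.670067,0.99142355,0.0072068621,0.0013695925
5.8790765,25.465444,25.215463,0.9900886,0.008458897,0.0014525052
6.2051957,21.675742,21.429759,0.9885343,0.0099256061,0.0015400928
6.549405,18.454834,18.212518,0.98672464,0.011642826,0.0016325354
6.9127081,15.717329,15.478384,0.98461796,0.013652036,0.0017299992
7.296164,13.390658,13.154818,0.98216625,0.016001123,0.0018326294
7.7008907,11.413142,11.180174,0.97931425,0.018745209,0.0019405428
8.128068,9.7323672,9.5020603,0.97599866,0.021947523,0.0020538176
8.5789413,8.3037844,8.0759537,0.97214722,0.025680293,0.002172482
9.0548251,7.0895341,6.864016,0.96767787,0.030025633,0.0022965
9.5571067,6.0574399,5.8340903,0.96249789,0.035076356,0.002425755
10.08725,5.1801558,4.9588484,0.95650331,0.040936659,0.0025600304
10.646802,4.4344407,4.2150657,0.94957844,0.047722574,0.0026989883
11.237392,3.8005424,3.5830048,0.94159579,0.055562064,0.0028421445
11.860743,3.2616737,3.0458919,0.93241656,0.064594599,0.0029888432
12.518673,2.8035672,2.589472,0.92189173,0.074970039,0.0031382286
13.213098,2.414097,2.2016307,0.90986418,0.086846597,0.0032892185
13.946044,2.0829574,1.8720724,0.89617187,0.10038765,0.0034404794
14.719647,1.8013893,1.5920477,0.88065238,0.11575721,0.0035904069
15.536163,1.5619483,1.3541208,0.8631491,0.13311378,0.0037371151
16.397971,1.3583074,1.1519726,0.84351892,0.15260264,0.0038784392
17.307586,1.1850888,0.98023292,0.82164157,0.17434648,0.004011955
18.267658,1.0377219,0.83433774,0.79743026,0.19843471,0.0041350224
19.280986,0.91232184,0.71040851,0.77084312,0.22491202,0.0042448531
20.350524,0.8055868,0.60514907,0.74189447,0.25376693,0.0043386068
21.479391,0.7147102,0.51575817,0.71066494,0.28492155,0.0044135144
22.670878,0.63730656,0.43985519,0.67730905,0.31822393,0.0044670215
23.928458,0.57134823,0.37541699,0.64205877,0.35344429,0.0044969436
25.255797,0.5151117,0.32072415,0.60522192,0.39027646,0.0045016198
26.656765,0.46713195,0.27431547,0.56717475,0.4283452,0.0044800468
28.135447,0.42616367,0.23494906,0.52834845,0.46721957,0.0044319781
29.696153,0.39114827,0.20156951,0.48921058,0.50643145,0.0043579727
31.343432,0.36118591,0.17327981,0.45024288,0.54549773,0.0042593862
33.082089,0.33551163,0.14931759,0.41191772,0.58394398,0.0041383016
34.917191,0.31347518,0.12903487,0.3746755,0.62132709,0.0039974079
36.854087,0.29452376,0.11188087,0.33890542,0.65725474,0.0038398404
38.898426,0.27818748,0.097387435,0.30493106,0.69139994,0.003669001
41.056167,0.26406688,0.085156577,0.27300193,0.7235097,0.0034883767
43.3336,0.25182241,0.074849947,0.24329079,0.75340784,0.0033013748
45.737365,0.24116546,0.066179861,0.21589637,0.78099244,0.0031111863
48.274469,0.23185072,0.058901681,0.1908501,0.80622921,0.002920684
50.95231,0.22366973,0.05280734,0.16812567,0.82914197,0.0027323586
53.778693,0.21644538,0.047719835,0.14764995,0.84980176,0.0025482878
56.76186,0.21002721,0.043488555,0.12931427,0.86831559,0.0023701353
59.910505,0.20428745,0.039985304,0.11298499,0.88481584,0.0021991706
63.23381,0.19911763,0.03710093,0.098512901,0.89945079,0.0020363048
66.741463,0.19442576,0.034742451,0.085741174,0.91237669,0.0018821343
70.443689,0.19013381,0.032830626,0.074511666,0.92375135,0.0017369885
74.351282,0.18617572,0.031297878,0.064669722,0.9337293,0.0016009773
78.475633,0.18249556,0.030086548,0.05606762,0.94245835,0.001474035
82.828767,0.17904611,0.029147396,0.048566851,0.95007719,0.0013559608
87.423375,0.1757875,0.028438337,0.042039469,0.95671408,0.001246453
92.27285,0.17268622,0.027923371,0.036368714,0.96248615,0.0011451388
97.391332,0.16971409,0.02757167,0.031449093,0.96749931,0.0010515981
102.79374,0.16684755,0.027356806,0.027186079,0.97184854,0.00096538323
108.49583,0.16406698,0.027256099,0.02349555,0.97561842,0.00088603382
114.51422,0.16135609,0.027250061,0.020303077,0.97888383,0.00081308891
120.86645,0.15870143,0.027321929,0.017543117,0.98171079,0.00074609554
127.57106,0.15609203,0.027457265,0.015158188,0.9841572,0.00068461508
134.64757,0.15351896,0.027643622,0.013098042,0.98627373,0.00062822766
142.11663,0.15097509,0.027870257,0.011318881,0.98810458,0.00057653502
150,0.14845476,0.028127892,0.0097826177,0.98968822,0.00052916214
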