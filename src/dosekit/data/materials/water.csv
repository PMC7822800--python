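energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,40.31581,40.048016,0.99330576,0.0054108069,0.0012834334
5.2773558,34.297493,34.035084,0.99228486,0.0063535783,0.0013615646
5.5700968,29.182537,28.925038,0.99109686,0.0074589307,0.0014442072
5.8790765,24.835321,24.582307,0.98971411,0.0087543302,0.0015315622
6.2051957,21.140588,20.891678,0.98810449,0.010271684,0.0016238252
6.549405,18.000383,17.755237,0.98623083,0.012047987,0.0017211807
6.9127081,15.331459,15.08977,0.98405016,0.014126039,0.0018237976
7.296164,13.063065,12.824562,0.98151296,0.016555221,0.0019318212
7.7008907,11.135072,10.899512,0.9785623,0.019392338,0.0020453652
8.128068,9.4963797,9.2635468,0.975133,0.022702497,0.0021645008
8.5789413,8.1035566,7.8732601,0.97115076,0.02656,0.0022892438
9.0548251,6.919693,6.691764,0.96653124,0.031049224,0.0024195399
9.5571067,5.9134195,5.6877094,0.96117934,0.03626541,0.0025552466
10.08725,5.0580759,4.8344543,0.95498857,0.042315314,0.0026961129
10.646802,4.331004,4.1093574,0.94784066,0.049317589,0.0028417556
11.237392,3.7129468,3.4931768,0.93960558,0.057402781,0.0029916342
11.860743,3.187538,2.9695602,0.93014219,0.066712783,0.0031450224
12.518673,2.7408678,2.5246105,0.91929949,0.07739953,0.0033009802
13.213098,2.3611144,2.1465175,0.90691894,0.089622734,0.0034583255
13.946044,2.0382303,1.8252442,0.89283796,0.10354643,0.0036156097
14.719647,1.763676,1.5522609,0.87689481,0.11933409,0.0037710987
15.536163,1.5301936,1.3203186,0.85893507,0.13714217,0.0039227645
16.397971,1.3316144,1.123257,0.83881972,0.15711199,0.0040682912
17.307586,1.1626955,0.9558405,0.81643482,0.17936008,0.0042051009
18.267658,1.0189807,0.81361995,0.79170238,0.20396722,0.0043304034
19.280986,0.89668242,0.69281416,0.7645918,0.23096693,0.0044412737
20.350524,0.79258146,0.59020972,0.73513108,0.26033416,0.0045347588
21.479391,0.70394147,0.50307575,0.70341648,0.29197551,0.0046080103
22.670878,0.62843666,0.42909144,0.66961932,0.32572224,0.0046584387
23.928458,0.56409008,0.36628443,0.63398856,0.36132757,0.0046838753
25.255797,0.50922132,0.31297851,0.59684795,0.39846932,0.0046827299
26.656765,0.46240197,0.26774916,0.55858723,0.43675864,0.0046541236
28.135447,0.42241782,0.22938569,0.5196475,0.47575451,0.0045979819
29.696153,0.38823674,0.1968592,0.48050161,0.51498332,0.0045150728
31.343432,0.35898132,0.16929519,0.44163149,0.55396153,0.0044069837
33.082089,0.3339057,0.14595043,0.40350455,0.59221941,0.004276036
34.917191,0.31237584,0.12619322,0.3665517,0.62932316,0.004125149
36.854087,0.29385273,0.1094866,0.33114891,0.66489342,0.003957667
38.898426,0.27787818,0.095374157,0.29760418,0.69861865,0.0037771692
41.056167,0.26406267,0.083467889,0.26615024,0.73026248,0.0035872841
43.3336,0.2520751,0.073437928,0.23694323,0.75966525,0.0033915227
45.737365,0.24163405,0.065003797,0.21006637,0.78674049,0.0031931436
48.274469,0.23250031,0.057926982,0.18553743,0.81146752,0.002995056
50.95231,0.2244706,0.052004618,0.16331873,0.83388151,0.0027997606
53.778693,0.21737222,0.047064121,0.14332825,0.85406242,0.0026093253
56.76186,0.21105845,0.042958636,0.12545082,0.87212379,0.0024253892
59.910505,0.20540469,0.039563156,0.10954846,0.88820235,0.0022491878
63.23381,0.2003052,0.036771234,0.095469538,0.90244887,0.0020815926
66.741463,0.19567027,0.034492191,0.083056304,0.91502054,0.0019231582
70.443689,0.19142384,0.032648735,0.072150912,0.92607492,0.0017741721
74.351282,0.18750149,0.031174949,0.062599882,0.93576542,0.0016347033
78.475633,0.18384874,0.030014578,0.054257275,0.94423808,0.001504648
82.828767,0.18041955,0.029119573,0.046986755,0.95162948,0.0013837699
87.423375,0.17717509,0.028448863,0.040662753,0.95806551,0.0012717352
92.27285,0.1740827,0.027967304,0.035170959,0.9636609,0.001168142
97.391332,0.17111498,0.027644795,0.030408304,0.96851915,0.001072544
102.79374,0.16824901,0.027455522,0.026282588,0.97273294,0.00098447014
108.49583,0.16546568,0.027377327,0.022711881,0.97638468,0.0009034394
114.51422,0.16274918,0.027391163,0.019623777,0.97954725,0.00082897233
120.86645,0.16008649,0.027480637,0.016954584,0.98228482,0.00076059957
127.57106,0.15746695,0.027631627,0.014648488,0.98465364,0.00069786793
134.64757,0.15488194,0.027831952,0.012656739,0.98670292,0.00064034462
142.11663,0.15232458,0.028071094,0.010936869,0.98847551,0.00058761984
150,0.14978944,0.028339964,0.0094519674,0.99000872,0.00053930835
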