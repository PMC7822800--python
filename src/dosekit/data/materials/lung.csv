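energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,41.876315,41.61111,0.99361746,0.0051659755,0.0012165618
5.2773558,35.623371,35.36347,0.99264294,0.0060663732,0.0012906828
5.5700968,30.309022,30.053958,0.99150875,0.0071221491,0.0013690979
5.8790765,25.792357,25.541713,0.99018841,0.0083595912,0.0014520023
6.2051957,21.953622,21.707021,0.98865116,0.0098092522,0.0015395863
6.549405,18.691042,18.448149,0.98686139,0.011506576,0.0016320318
6.9127081,15.91812,15.678634,0.9847779,0.013492595,0.0017295067
7.296164,13.561347,13.325001,0.98235315,0.015814688,0.0018321588
7.7008907,11.558248,11.324803,0.97953249,0.018527404,0.0019401076
8.128068,9.8557295,9.6249738,0.97625323,0.021693334,0.002053435
8.5789413,8.4086666,8.180412,0.97244383,0.025383996,0.0021721734
9.0548251,7.1787097,6.9527901,0.96802298,0.029680729,0.0022962921
9.5571067,6.133266,5.9095353,0.96289881,0.03467551,0.0024256806
10.08725,5.2446358,5.0229659,0.95696822,0.040471654,0.0025601298
10.646802,4.4892773,4.2695565,0.95011641,0.047184283,0.0026993102
11.237392,3.8471826,3.6293143,0.9422168,0.054940452,0.0028427477
11.860743,3.3013474,3.0852487,0.93313143,0.063878774,0.0029897976
12.518673,2.8373196,2.6229202,0.92271203,0.074148356,0.0031396169
13.213098,2.4428166,2.2300574,0.91080202,0.08590684,0.003291137
13.946044,2.1073991,1.8962317,0.89723964,0.099317317,0.0034430389
14.719647,1.8221949,1.6125804,0.88186239,0.11454388,0.0035937329
15.536163,1.5796632,1.3715715,0.86451301,0.13174564,0.0037413472
16.397971,1.3733951,1.1668042,0.84504715,0.15106912,0.003883729
17.307586,1.1979433,0.99283862,0.82334255,0.17263898,0.0040184636
18.267658,1.0486781,0.84505187,0.7993096,0.19654748,0.0041429149
19.280986,0.92166438,0.71951515,0.7729027,0.22284301,0.0042542921
20.350524,0.81355753,0.61288965,0.74413162,0.25151864,0.0043497444
21.479391,0.72151471,0.52233787,0.71307175,0.28250176,0.0044264821
22.670878,0.64311959,0.44544839,0.67987188,0.3156462,0.0044819196
23.928458,0.5763183,0.38017186,0.6447581,0.35072807,0.0045138309
25.255797,0.51936505,0.32476666,0.60803265,0.38744685,0.0045205043
26.656765,0.47077586,0.27775263,0.57006691,0.42543221,0.0045008787
28.135447,0.42928933,0.23787185,0.53128838,0.46425697,0.0044546471
29.696153,0.39383319,0.20405523,0.49216247,0.50345522,0.0043823088
31.343432,0.36349596,0.17539416,0.45317049,0.54254434,0.0042851656
33.082089,0.3375028,0.15111641,0.41478613,0.58104861,0.0041652562
34.917191,0.31519505,0.13056561,0.37745278,0.61852199,0.0040252384
36.854087,0.29601278,0.11318387,0.34156389,0.65456788,0.0038682313
38.898426,0.27948001,0.09849697,0.30744827,0.6888541,0.003697635
41.056167,0.26519214,0.086101776,0.27536108,0.72112197,0.0035169488
43.3336,0.25280522,0.075655569,0.24548082,0.75118958,0.0033296038
45.737365,0.24202691,0.066866949,0.21791159,0.77894958,0.003138823
48.274469,0.23260875,0.059488118,0.19268963,0.80436285,0.0029475171
50.95231,0.22433958,0.053308326,0.16979265,0.82744913,0.0027582167
53.778693,0.21703998,0.048148287,0.14915075,0.84827621,0.0025730394
56.76186,0.21055756,0.043855451,0.13065762,0.86694869,0.0023936863
59.910505,0.2047629,0.040299976,0.11418123,0.88359731,0.0022214611
63.23381,0.19954612,0.037371307,0.099573346,0.89836935,0.0020573046
66.741463,0.19481402,0.034975273,0.086677539,0.91142062,0.0019018382
70.443689,0.19048758,0.033031617,0.075335646,0.92290894,0.0017554118
74.351282,0.18649985,0.031471907,0.065392673,0.93298918,0.0016181511
78.475633,0.1827942,0.03023775,0.056700329,0.94180967,0.0014900028
82.828767,0.17932275,0.029279282,0.049119393,0.94950983,0.0013707744
87.423375,0.17604513,0.028553893,0.042521127,0.9562187,0.0012601704
92.27285,0.17292735,0.028025132,0.036787942,0.96205424,0.0011578212
97.391332,0.16994087,0.027661788,0.03181352,0.96712317,0.0010633084
102.79374,0.16706181,0.02743711,0.027502538,0.97152128,0.0009761842
108.49583,0.16427026,0.02732814,0.023770123,0.97533389,0.00089598744
114.51422,0.16154969,0.027315155,0.020541144,0.9786366,0.00082225521
120.86645,0.15888648,0.027381192,0.017749423,0.98149605,0.00075453212
127.57106,0.15626946,0.027511643,0.015336896,0.98397073,0.00069237673
134.64757,0.15368957,0.027693915,0.013252797,0.98611184,0.00063536613
142.11663,0.15113956,0.027917143,0.011452867,0.98796403,0.00058309888
150,0.14861367,0.028171945,0.0098986053,0.9895662,0.0005351968
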