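energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,207.88034,207.57779,0.99853589,0.00091081966,0.00055328797
5.2773558,176.70063,176.40959,0.99834213,0.0010704122,0.00058746019
5.5700968,150.20204,149.92143,0.99811842,0.0012578596,0.00062372423
5.8790765,127.68173,127.41058,0.9978598,0.0014779928,0.00066220366
6.2051957,108.54241,108.27985,0.9975605,0.0017364715,0.00070302828
6.549405,92.27644,92.021681,0.99721374,0.0020399232,0.00074633413
6.9127081,78.452428,78.204762,0.99681163,0.0023961052,0.0007922635
7.296164,66.703736,66.462529,0.99634494,0.002814092,0.00084096471
7.7008907,56.718781,56.483461,0.99580292,0.0033044921,0.00089259191
8.128068,48.232758,48.002814,0.995173,0.0038796986,0.00094730457
8.5789413,41.020623,40.795596,0.99444056,0.0045541768,0.0010052669
9.0548251,34.891119,34.670597,0.99358856,0.0053447952,0.0010666468
9.5571067,29.681704,29.46532,0.99259718,0.0062712027,0.0011316147
10.08725,25.254242,25.041667,0.9914434,0.0073562581,0.0012003419
10.646802,21.491335,21.282275,0.99010049,0.0086265156,0.0012729983
11.237392,18.29321,18.087405,0.98853748,0.01011277,0.0013497496
11.860743,15.575075,15.372293,0.98671858,0.011850663,0.0014307537
12.518673,13.264868,13.064903,0.98460249,0.013881355,0.0015161563
13.213098,11.301345,11.104016,0.98214166,0.01625225,0.0016060856
13.946044,9.6324569,9.4376048,0.97928158,0.019017775,0.0017006449
14.719647,8.2139695,8.0214545,0.9759599,0.022240197,0.0017999048
15.536163,7.0082887,6.8179891,0.97210566,0.025990449,0.001903893
16.397971,5.9834645,5.795275,0.96763848,0.030348936,0.0020125825
17.307586,5.1123434,4.9261735,0.96246786,0.035406266,0.0021258778
18.267658,4.371848,4.1876209,0.95649256,0.041263841,0.0022435986
19.280986,3.7423654,3.5600166,0.94960033,0.048034209,0.0023654617
20.350524,3.207227,3.0267031,0.94166787,0.055841074,0.0024910607
21.479391,2.7522661,2.5735242,0.93256136,0.064818793,0.0026198443
22.670878,2.3654429,2.1884493,0.92213768,0.075111224,0.0027510934
23.928458,2.0365246,1.861254,0.91024641,0.086869692,0.0028838989
25.255797,1.7568145,1.5832494,0.89673296,0.1002499,0.0030171416
26.656765,1.5189212,1.3470511,0.88144294,0.11540758,0.0031494758
28.135447,1.3165626,1.1463835,0.86422796,0.13249272,0.0032793206
29.696153,1.1443998,0.97591339,0.84495282,0.15164231,0.0034048621
31.343432,0.99789488,0.83110813,0.82350423,0.1729717,0.003524069
33.082089,0.87319114,0.7081157,0.79980057,0.19656471,0.0036347268
34.917191,0.76701065,0.60366243,0.77380233,0.22246318,0.0037344926
36.854087,0.67656743,0.51496609,0.74552247,0.25065656,0.0038209716
38.898426,0.59949359,0.43966214,0.71503562,0.28107257,0.0038918155
41.056167,0.53377663,0.375741,0.68248493,0.31357023,0.0039448377
43.3336,0.47770605,0.32149469,0.64808546,0.3479364,0.0039781381
45.737365,0.42982807,0.27547161,0.61212291,0.38388686,0.003990228
48.274469,0.38890714,0.23643796,0.57494711,0.42107275,0.0039801411
50.95231,0.35389315,0.20334508,0.53696014,0.45909234,0.003947518
53.778693,0.32389365,0.17530159,0.49859988,0.49750747,0.0038926535
56.76186,0.29815021,0.15154981,0.46032005,0.53586345,0.0038164974
59.910505,0.2760183,0.13144565,0.4225689,0.57371049,0.0037206097
63.23381,0.25695025,0.11444154,0.3857685,0.61062443,0.0036070722
66.741463,0.24048074,0.10007196,0.35029659,0.64622504,0.0034783677
70.443689,0.22621442,0.087941075,0.31647275,0.68019001,0.0033372397
74.351282,0.21381548,0.077712295,0.28454951,0.71226394,0.0031865477
78.475633,0.20299873,0.069099363,0.25470887,0.742262,0.0030291316
82.828767,0.19352201,0.061858795,0.22706356,0.77006875,0.0028676954
87.423375,0.18517974,0.055783462,0.2016623,0.79563298,0.0027047168
92.27285,0.17779751,0.050697128,0.17849782,0.81895979,0.0025423861
97.391332,0.17122735,0.046449815,0.15751643,0.840101,0.0023825714
102.79374,0.16534384,0.042913866,0.13862813,0.85914506,0.0022268089
108.49583,0.1600407,0.039980598,0.12171647,0.87620722,0.0020763111
114.51422,0.15522795,0.037557459,0.1066474,0.89142061,0.0019319899
120.86645,0.15082947,0.03556562,0.093276958,0.90492855,0.0017944876
127.57106,0.14678093,0.033937919,0.081457552,0.91687824,0.0016642131
134.64757,0.14302801,0.032617123,0.071042833,0.92741579,0.0015413787
142.11663,0.13952494,0.03155445,0.061891347,0.93668262,0.0014260361
150,0.13623316,0.030708312,0.053869054,0.94481284,0.0013181093
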