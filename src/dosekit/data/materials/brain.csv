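energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,41.611174,41.345938,0.99357589,0.0052168977,0.0012072122
5.2773558,35.398116,35.138116,0.99259313,0.0061261197,0.0012807529
5.5700968,30.117667,29.862444,0.99144923,0.007192223,0.0013585514
5.8790765,25.629816,25.378956,0.99011746,0.008441742,0.0014408003
6.2051957,21.815571,21.568705,0.9885668,0.0099055134,0.0015276878
6.549405,18.573805,18.330603,0.9867613,0.011619307,0.0016193928
6.9127081,15.818575,15.57874,0.98465939,0.013624525,0.0017160803
7.296164,13.47684,13.240108,0.98221314,0.015968969,0.0018178951
7.7008907,11.486522,11.25266,0.97936738,0.018707662,0.0019249534
8.128068,9.7948671,9.563665,0.97605894,0.021903726,0.0020373335
8.5789413,8.3570379,8.1283112,0.97221567,0.02562927,0.0021550642
9.0548251,7.1349295,6.9085149,0.96775562,0.029966274,0.0022781105
9.5571067,6.096157,5.8719107,0.96258623,0.035007412,0.002406358
10.08725,5.213197,4.9909934,0.95660367,0.040856733,0.0025395931
10.646802,4.4626581,4.2423876,0.9496924,0.047630118,0.002677482
11.237392,3.8246601,3.6062279,0.94172507,0.055455379,0.0028195463
11.860743,3.2823069,3.0656319,0.93256302,0.064471845,0.0029651371
12.518673,2.8212388,2.6062521,0.92205734,0.074829256,0.0031134079
13.213098,2.4292513,2.2158955,0.91005098,0.086685735,0.0032632873
13.946044,2.095972,1.8841998,0.89638192,0.10020462,0.003413455
14.719647,1.8125851,1.6023588,0.88088772,0.11554995,0.0035623218
15.536163,1.571598,1.3628887,0.86341163,0.13288035,0.0037080193
16.397971,1.3666426,1.1594292,0.84381028,0.15234132,0.0038484018
17.307586,1.1923064,0.98657528,0.82196304,0.1740559,0.0039810661
18.267658,1.0439892,0.83973346,0.7977826,0.198114,0.0041033934
19.280986,0.91778099,0.71500001,0.77122642,0.22456096,0.0042126172
20.350524,0.81035852,0.60905736,0.74230802,0.25338606,0.004305918
21.479391,0.7188971,0.51908612,0.71110711,0.28451234,0.0043805448
22.670878,0.64099579,0.44269024,0.67777723,0.31778881,0.004433958
23.928458,0.57461384,0.37783344,0.64254932,0.3529867,0.0044639834
25.255797,0.51801658,0.32278517,0.60573028,0.38980075,0.0044689643
26.656765,0.46972952,0.27607473,0.56769555,0.42785655,0.0044478957
28.135447,0.42849929,0.23645221,0.52887573,0.46672375,0.0044005224
29.696153,0.39326047,0.20285534,0.48973805,0.50593456,0.0043273891
31.343432,0.36310739,0.17438129,0.45076424,0.54500593,0.0042298314
33.082089,0.33727015,0.15026276,0.41242695,0.58346314,0.0041099084
34.917191,0.31509429,0.12984755,0.37516715,0.62086257,0.0039702825
36.854087,0.29602346,0.11258133,0.33937481,0.65681113,0.0038140617
38.898426,0.27958472,0.097992893,0.30537446,0.69098092,0.0036446205
41.056167,0.26537603,0.085681682,0.27341658,0.723118,0.0034654206
43.3336,0.25305565,0.07530715,0.24367496,0.7530452,0.0032798464
45.737365,0.2423331,0.066579751,0.21624924,0.78065969,0.003091069
48.274469,0.23296151,0.059253262,0.19117168,0.80592637,0.002901945
50.95231,0.22473106,0.053118267,0.16841665,0.8288684,0.0027149519
53.778693,0.2174635,0.047996617,0.14791157,0.84955627,0.0025321578
56.76186,0.21100739,0.043736726,0.12954816,0.86809662,0.0023552194
59.910505,0.20523414,0.040209571,0.11319304,0.88462156,0.0021854019
63.23381,0.2000346,0.03730529,0.098697145,0.89927924,0.0020236141
66.741463,0.19531616,0.034930304,0.085903713,0.91222584,0.0018704519
70.443689,0.19100031,0.033004858,0.074654579,0.92361918,0.0017262455
74.351282,0.18702053,0.031460941,0.064795019,0.93361387,0.0015911065
78.475633,0.18332057,0.030240522,0.056177204,0.94235782,0.0014649717
82.828767,0.17985286,0.029294043,0.048662492,0.94998986,0.0013476433
87.423375,0.17657732,0.028579152,0.042122795,0.95663838,0.0012388231
92.27285,0.17346018,0.028059615,0.036441204,0.96242065,0.0011381417
97.391332,0.17047309,0.027704409,0.031512079,0.96744274,0.0010451826
102.79374,0.16759236,0.027486938,0.027240752,0.97179975,0.00095950161
108.49583,0.1647982,0.027384376,0.023542969,0.97557639,0.00088064192
114.51422,0.16207423,0.027377114,0.020344178,0.97884768,0.00080814587
120.86645,0.15940691,0.027448281,0.017578724,0.98167971,0.00074156369
127.57106,0.1567852,0.027583348,0.015189023,0.98413052,0.00068045976
134.64757,0.15420011,0.027769792,0.013124737,0.98625085,0.00062441703
142.11663,0.15164443,0.027996802,0.011341989,0.98808497,0.00057303986
150,0.1491125,0.028255042,0.009802617,0.98967143,0.00052595569
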