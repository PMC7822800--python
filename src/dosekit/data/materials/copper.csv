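energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,2608.4859,2607.9453,0.99979209,6.8753986e-05,0.00013915496
5.2773558,2216.858,2216.3531,0.99977141,8.0814974e-05,0.00014777508
5.5700968,1884.0326,1883.5599,0.99974809,9.4986121e-05,0.00015692877
5.8790765,1601.1804,1600.7368,0.99972172,0.00011163526,0.00016664896
6.2051957,1360.7979,1360.3807,0.99969184,0.00013119401,0.0001769706
6.549405,1156.5084,1156.115,0.9996579,0.00015416878,0.00018793077
6.9127081,982.89236,982.52049,0.99961928,0.00018115356,0.00019956878
7.296164,835.34427,834.9919,0.99957523,0.00021284503,0.00021192636
7.7008907,709.95,709.61529,0.99952489,0.0002500601,0.00022504771
8.128068,603.38319,603.06447,0.99946726,0.00029375647,0.00023897973
8.5789413,512.81689,512.51267,0.99940117,0.00034505663,0.00025377208
9.0548251,435.84866,435.55758,0.99932525,0.00040527593,0.0002694774
9.5571067,370.43676,370.15761,0.99923789,0.00047595529,0.00028615141
10.08725,314.84603,314.57772,0.99913725,0.00055889941,0.00030385308
10.646802,267.60184,267.34339,0.99902113,0.00065622123,0.0003226448
11.237392,227.45097,227.2015,0.99888701,0.00077039386,0.0003425925
11.860743,193.32839,193.08709,0.99873192,0.00090431086,0.00036376585
12.518673,164.32896,164.09513,0.99855241,0.0010613565,0.00038623831
13.213098,139.68345,139.45645,0.99834443,0.0012454871,0.00041008737
13.946044,118.73815,118.5174,0.99810328,0.0014613258,0.00043539454
14.719647,100.93747,100.72247,0.99782348,0.0017142724,0.00046224552
15.536163,85.809277,85.599555,0.99749864,0.0020106297,0.00049073022
16.397971,72.952294,72.747444,0.99712131,0.0023577503,0.00052094274
17.307586,62.025515,61.825171,0.99668281,0.0027642055,0.00055298132
18.267658,52.739129,52.542965,0.99617307,0.0032399799,0.00058694823
19.280986,44.846838,44.654565,0.99558036,0.0037966938,0.00062294946
20.350524,38.139327,37.950689,0.99489105,0.0044478589,0.00066109446
21.479391,32.438706,32.253477,0.99408934,0.0052091685,0.00070149554
22.670878,27.593798,27.411776,0.9931569,0.0060988283,0.00074426717
23.928458,23.476119,23.297131,0.99207255,0.0071379287,0.00078952508
25.255797,19.976481,19.800373,0.99081175,0.0083508645,0.00083738494
26.656765,17.002087,16.828726,0.98934624,0.0097658019,0.00088796083
28.135447,14.474073,14.303344,0.98764344,0.011415196,0.00094136313
29.696153,12.325416,12.15722,0.98566595,0.013336355,0.00099769606
31.343432,10.499156,10.333409,0.98337089,0.015572058,0.0010570544
33.082089,8.9468847,8.7835157,0.98070928,0.018171199,0.0011195198
34.917191,7.6274621,7.4664125,0.97762538,0.021189468,0.0011851559
36.854087,6.5059244,6.3471462,0.97405596,0.024690035,0.0012540025
38.898426,5.5525574,5.3960123,0.96992971,0.028744219,0.0013260694
41.056167,4.742108,4.5877663,0.96516658,0.033432089,0.0014013279
43.3336,4.0531145,3.9009542,0.95967734,0.038842958,0.001479702
45.737365,3.4673375,3.3173432,0.95336324,0.0450757,0.0015610575
48.274469,2.9692756,2.8214384,0.94611602,0.05223879,0.0016451913
50.95231,2.5457553,2.4000709,0.93781821,0.060449975,0.0017318177
53.778693,2.1855803,2.0420495,0.92834401,0.069835435,0.0018205556
56.76186,1.8792357,1.737863,0.91756078,0.080528305,0.0019109149
59.910505,1.6186351,1.479428,0.90533132,0.092666395,0.0020022834
63.23381,1.3969061,1.2598751,0.89151712,0.10638896,0.0020939157
66.741463,1.2082082,1.0733659,0.87598266,0.12183241,0.0021849249
70.443689,1.047578,0.91493843,0.85860087,0.13912485,0.0022742795
74.351282,0.91079728,0.78037582,0.8392597,0.15837949,0.0023608064
78.475633,0.79428132,0.66609402,0.81786975,0.17968705,0.0024432036
82.828767,0.69498379,0.56904697,0.79437254,0.2031074,0.002520062
87.423375,0.6103159,0.48664581,0.76874908,0.22866102,0.0025899008
92.27285,0.53807777,0.4166902,0.74102804,0.25632075,0.0026512132
97.391332,0.47640004,0.35731,0.71129261,0.28600486,0.0027025256
102.79374,0.42369427,0.30691568,0.67968532,0.31757221,0.0027424638
108.49583,0.37861078,0.26415621,0.64640976,0.35082042,0.0027698256
114.51422,0.34000283,0.22788324,0.61172855,0.3854878,0.0027836509
120.86645,0.30689613,0.19712069,0.57595727,0.42125944,0.0027832857
127.57106,0.27846301,0.17103886,0.53945418,0.45777739,0.0027684302
134.64757,0.25400037,0.14893252,0.50260652,0.49465431,0.0027391678
142.11663,0.23291101,0.13020217,0.46581434,0.53148969,0.0026959689
150,0.2146877,0.11433821,0.42947323,0.5678871,0.0026396699
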