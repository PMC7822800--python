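energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,24.696325,24.440293,0.98954805,0.0088440547,0.0016078913
5.2773558,21.022739,20.770918,0.98791671,0.010378577,0.0017047144
5.5700968,17.900504,17.652536,0.9860178,0.012175328,0.0018068727
5.8790765,15.246852,15.002414,0.98380774,0.014277719,0.0019145404
6.2051957,12.991438,12.750242,0.98123628,0.016735852,0.0020278666
6.549405,11.074478,10.836267,0.97824567,0.019607368,0.0021469663
6.9127081,9.4451655,9.2097104,0.97476974,0.022958348,0.0022719085
7.296164,8.0603181,7.8274152,0.97073308,0.026864218,0.0024027032
7.7008907,6.8832378,6.6527063,0.96605008,0.031410639,0.0025392849
8.128068,5.882735,5.6544153,0.9606242,0.036694311,0.0026814939
8.5789413,5.0323025,4.8060538,0.95434733,0.042823616,0.0028290541
9.0548251,4.309412,4.085111,0.94709945,0.049919,0.0029815485
9.5571067,3.6949169,3.4724558,0.93874866,0.058112952,0.0031383915
10.08725,3.1725445,2.9518302,0.9291518,0.067549403,0.0032987999
10.646802,2.728465,2.5094172,0.91815587,0.078382365,0.0034617621
11.237392,2.3509239,2.1334746,0.90560042,0.090773568,0.0036260093
11.860743,2.0299315,1.8140234,0.89132115,0.10488886,0.0037899895
12.518673,1.756997,1.542583,0.87515499,0.12089316,0.0039518484
13.213098,1.524904,1.3119463,0.85694682,0.13894376,0.0041094213
13.946044,1.3275193,1.1159882,0.83655779,0.15918197,0.0042602418
14.719647,1.1596297,0.94950366,0.81387526,0.18172317,0.0044015703
15.536163,1.0168046,0.80806906,0.78882393,0.20664562,0.0045304504
16.397971,0.89527799,0.68792506,0.76137756,0.23397865,0.0046437932
17.307586,0.79184896,0.58587685,0.73157024,0.26369126,0.004738494
18.267658,0.70379678,0.49920934,0.6995061,0.29568233,0.0048115755
19.280986,0.62880887,0.42561517,0.66536587,0.32977378,0.0048603531
20.350524,0.5649195,0.36313343,0.62940908,0.36570831,0.0048826075
21.479391,0.51045777,0.31009768,0.59197062,0.40315263,0.0048767497
22.670878,0.46400331,0.26509169,0.55345115,0.44170689,0.0048419589
23.928458,0.42434874,0.22691189,0.51430157,0.48092015,0.0047782752
25.255797,0.39046767,0.1945354,0.47500271,0.52031066,0.0046866324
26.656765,0.36148756,0.16709294,0.43604188,0.55938929,0.0045688249
28.135447,0.33666665,0.14384569,0.39788893,0.59768366,0.0044274093
29.696153,0.31537432,0.12416576,0.3609741,0.63476035,0.004265553
31.343432,0.29707443,0.10751945,0.3256698,0.67024335,0.0040868463
33.082089,0.28131116,0.093453158,0.29227804,0.70382686,0.003895099
34.917191,0.26769699,0.081581318,0.26102377,0.73528208,0.0036941444
36.854087,0.25590244,0.071576163,0.23205425,0.76445808,0.0034876656
38.898426,0.24564737,0.063159042,0.20544342,0.79127752,0.0032790576
41.056167,0.23669364,0.056093032,0.18119999,0.81572868,0.0030713299
43.3336,0.22883879,0.050176657,0.15927789,0.83785506,0.0028670503
45.737365,0.22191073,0.045238555,0.13958773,0.85774395,0.002668324
48.274469,0.21576319,0.041132942,0.12200808,0.87551512,0.0024768027
50.95231,0.21027189,0.037735758,0.10639596,0.89131033,0.002293715
53.778693,0.20533125,0.034941394,0.092595887,0.9052842,0.0021199104
56.76186,0.20085162,0.032659908,0.08044736,0.91759673,0.0019559111
59.910505,0.19675693,0.030814665,0.069790691,0.92840734,0.0018019649
63.23381,0.19298265,0.029340325,0.060471351,0.93787055,0.0016580972
66.741463,0.18947412,0.028181142,0.05234298,0.94613286,0.001524159
70.443689,0.18618506,0.027289512,0.045269312,0.95333082,0.0013998684
74.351282,0.1830764,0.026624749,0.039125217,0.95958994,0.0012848475
78.475633,0.18011516,0.026152038,0.033797086,0.96502426,0.001178652
82.828767,0.1772736,0.025841555,0.029182726,0.96973648,0.0010807959
87.423375,0.17452846,0.025667711,0.025190922,0.97381831,0.00099077123
92.27285,0.1718603,0.025608523,0.021740782,0.97735116,0.00090806301
97.391332,0.16925294,0.025645073,0.018760953,0.98040689,0.00083216072
102.79374,0.16669303,0.025761053,0.016188778,0.98304866,0.0007625668
108.49583,0.1641696,0.02594238,0.013969446,0.98533175,0.00069880259
114.51422,0.16167373,0.02617687,0.012055157,0.98730443,0.00064041233
120.86645,0.15919826,0.026453964,0.010404336,0.9890087,0.00058696568
127.57106,0.15673755,0.026764497,0.0089809038,0.99048104,0.00053805896
134.64757,0.15428723,0.0271005,0.0077536026,0.99175308,0.00049331562
142.11663,0.151844,0.027455033,0.0066953961,0.99285222,0.00045238595
150,0.14940552,0.027822051,0.0057829265,0.99380213,0.0004149464
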