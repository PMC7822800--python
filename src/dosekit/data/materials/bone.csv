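energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,253.50829,253.20821,0.99880867,0.00079801675,0.00039331037
5.2773558,215.4785,215.18846,0.99864451,0.00093787198,0.00041761445
5.5700968,183.15847,182.87754,0.99845444,0.0011021465,0.00044340884
5.8790765,155.6909,155.41824,0.99823414,0.0012950788,0.00047078218
6.2051957,132.34723,132.08208,0.99797854,0.0015216354,0.00049982767
6.549405,112.50827,112.24995,0.99768172,0.0017876338,0.00053064321
6.9127081,95.647806,95.395714,0.99733678,0.0020998854,0.00056333137
7.296164,81.318644,81.072231,0.99693564,0.0024663612,0.00059799936
7.7008907,69.140723,68.899498,0.99646886,0.0028963834,0.00063475895
8.128068,58.791051,58.554576,0.99592543,0.0034008479,0.00067372618
8.5789413,49.995131,49.763011,0.9952925,0.0039924802,0.00071502106
9.0548251,42.51968,42.291564,0.9945551,0.0046861298,0.00075876703
9.5571067,36.166442,35.942014,0.9936958,0.0054991078,0.00080509023
10.08725,30.766926,30.545908,0.99269431,0.006451572,0.00085411851
10.646802,26.17794,25.960082,0.99152706,0.0075669644,0.00090598013
11.237392,22.277791,22.062873,0.99016669,0.0088725055,0.00096080204
11.860743,18.963056,18.750883,0.98858154,0.010399748,0.0010187077
12.518673,16.145842,15.936241,0.98673499,0.012185194,0.0010798145
13.213098,13.75145,13.544271,0.9845848,0.014270969,0.0011442297
13.946044,11.716398,11.511508,0.98208239,0.016705559,0.0012120472
14.719647,9.9867323,9.7840178,0.97917206,0.019544594,0.0012833412
15.536163,8.5166025,8.3159645,0.97579018,0.022851659,0.0013581604
16.397971,7.2670402,7.0683946,0.97186436,0.026699122,0.0014365203
17.307586,6.2049278,6.0082034,0.96731269,0.031168921,0.001518394
18.267658,5.3021196,5.1072575,0.96204302,0.036353274,0.0016037018
19.280986,4.5346953,4.3416473,0.95595247,0.042355233,0.0016922983
20.350524,3.8823258,3.6910537,0.94892706,0.049288979,0.0017839593
21.479391,3.3277337,3.1382086,0.94084188,0.057279755,0.0018783661
22.670878,2.8562355,2.6684365,0.93156165,0.066463263,0.0019750892
23.928458,2.4553517,2.2692658,0.92094205,0.076984377,0.002073571
25.255797,2.1144763,1.9300973,0.90883194,0.088994955,0.0021731099
26.656765,1.8245955,1.6419234,0.8950766,0.10265056,0.002272845
28.135447,1.5780484,1.3970891,0.87952236,0.1181059,0.002371745
29.696153,1.368324,1.1890885,0.86202258,0.13550882,0.002468603
31.343432,1.1898889,1.0123927,0.84244507,0.15499289,0.0025620388
33.082089,1.0380399,0.86230309,0.82068096,0.17666852,0.0026505132
34.917191,0.90877992,0.73482623,0.7966546,0.20061304,0.0027323554
36.854087,0.79871188,0.62656837,0.77033396,0.22686023,0.0028058062
38.898426,0.70494848,0.53464523,0.74174087,0.25539005,0.0028690778
41.056167,0.62503584,0.4566055,0.71095984,0.28611974,0.0029204292
43.3336,0.55688838,0.39036583,0.67814448,0.31889727,0.0029582533
45.737365,0.49873358,0.33415556,0.64352018,0.35349865,0.0029811703
48.274469,0.44906501,0.28646978,0.60738206,0.38962982,0.0029881203
50.95231,0.40660239,0.24602936,0.57008767,0.42693389,0.0029784428
53.778693,0.37025767,0.2117471,0.53204445,0.46500362,0.0029519367
56.76186,0.33910619,0.18269887,0.49369264,0.50339847,0.0029088899
59.910505,0.3123622,0.15809909,0.45548523,0.5416647,0.0028500759
63.23381,0.28935803,0.13727997,0.41786658,0.57935671,0.0027767147
66.741463,0.26952635,0.11967377,0.38125218,0.61605742,0.0026904038
70.443689,0.25238521,0.10479782,0.34601113,0.65139584,0.002593025
74.351282,0.23752517,0.092241666,0.31245302,0.68506034,0.0024866397
78.475633,0.2245985,0.0816563,0.28081992,0.7168067,0.0023733814
82.828767,0.21330992,0.072744881,0.25128358,0.74646106,0.0022553567
87.423375,0.20340874,0.065254925,0.22394736,0.77391808,0.002134561
92.27285,0.19468221,0.058971633,0.19885187,0.79913531,0.0020128148
97.391332,0.18694984,0.053712245,0.17598322,0.82212506,0.0018917201
102.79374,0.18005856,0.049321227,0.15528266,0.8429447,0.0017726382
108.49583,0.17387865,0.045666193,0.13665669,0.86168663,0.0016566834
114.51422,0.16830022,0.042634435,0.11998663,0.87846864,0.0015447315
120.86645,0.16323026,0.040129982,0.10513741,0.89342515,0.0014374373
127.57106,0.15859011,0.03807109,0.091964927,0.90669981,0.0013352585
134.64757,0.15431333,0.036388128,0.080322145,0.91843937,0.0012384827
142.11663,0.15034383,0.035021763,0.070063776,0.92878897,0.0011472543
150,0.14663434,0.033921434,0.061049746,0.93788865,0.0010616014
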