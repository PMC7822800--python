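energy_keV,mu_rho,muen_rho,f_photo,f_compton,f_rayleigh
5,39.932144,39.686639,0.9938049,0.0049126378,0.0012824649
5.2773558,33.968132,33.727926,0.99287023,0.0057691129,0.001360656
5.5700968,28.899334,28.663956,0.99178313,0.0067734778,0.0014433913
5.8790765,24.591354,24.360381,0.99051833,0.0079507886,0.0015308808
6.2051957,20.929972,20.703025,0.98904649,0.0093301797,0.0016233309
6.549405,17.818118,17.594858,0.98733359,0.010945469,0.0017209402
6.9127081,15.173295,14.953418,0.98534028,0.012835829,0.001823894
7.296164,12.925391,12.708625,0.98302111,0.015046528,0.0019323585
7.7008907,11.01482,10.800923,0.98032379,0.017629734,0.0020464725
8.128068,9.3909404,9.1796969,0.9771883,0.020645364,0.0021663375
8.5789413,8.0107145,7.8019332,0.97354602,0.024161975,0.0022920065
9.0548251,6.837565,6.6310763,0.96931888,0.02825765,0.0024234694
9.5571067,5.8404054,5.6360598,0.96441852,0.033020848,0.0025606364
10.08725,4.9928162,4.7904821,0.95874554,0.038551145,0.0027033185
10.646802,4.2723435,4.0719057,0.95218901,0.044959782,0.0028512056
11.237392,3.6599042,3.4612626,0.94462624,0.052369916,0.0030038406
11.860743,3.1392797,2.9423477,0.93592299,0.060916418,0.0031605924
12.518673,2.6966857,2.5013893,0.92593433,0.070745043,0.0033206267
13.213098,2.3204072,2.1266837,0.91450634,0.082010784,0.0034828766
13.946044,2.0004873,1.8082843,0.90147882,0.094875163,0.0036460146
14.719647,1.7284636,1.5377385,0.88668932,0.10950225,0.0038084289
15.536163,1.4971439,1.3078625,0.86997862,0.12605317,0.0039682082
16.397971,1.3004152,1.1125514,0.85119779,0.14467907,0.0041231379
17.307586,1.1330819,0.94661706,0.83021694,0.16551234,0.0042707138
18.267658,0.99072829,0.80565028,0.80693536,0.18865646,0.004408178
19.280986,0.86960093,0.68590397,0.78129261,0.21417481,0.0045325812
20.350524,0.76650973,0.58419369,0.75328,0.24207912,0.0046408744
21.479391,0.67874317,0.49781318,0.72295128,0.27231869,0.0047300301
22.670878,0.60399654,0.42446252,0.69043127,0.30477154,0.004797189
23.928458,0.54031083,0.36218714,0.65592114,0.33923904,0.0048398233
25.255797,0.48602089,0.30932595,0.61969896,0.37544514,0.0048559046
26.656765,0.43971128,0.26446723,0.5821146,0.41304134,0.0048440584
28.135447,0.40017885,0.22641125,0.54357861,0.4516177,0.0048036874
29.696153,0.36640088,0.19413835,0.50454556,0.49071939,0.0047350467
31.343432,0.33750796,0.16678196,0.46549313,0.52986761,0.0046392594
33.082089,0.31276105,0.14360555,0.42689889,0.56858284,0.0045182672
34.917191,0.29153191,0.12398312,0.38921717,0.60640811,0.0043747212
36.854087,0.27328646,0.10738259,0.35285832,0.64292985,0.0042118243
38.898426,0.25757072,0.093351683,0.31817231,0.67779454,0.0040331444
41.056167,0.24399875,0.081505932,0.28543792,0.71071966,0.0038424176
43.3336,0.2322425,0.071518485,0.25485783,0.74149881,0.0036433624
45.737365,0.22202311,0.063111441,0.2265593,0.77000118,0.0034395195
48.274469,0.21310358,0.056048491,0.20059944,0.79616643,0.0032341273
50.95231,0.2052825,0.050128661,0.17697379,0.81999618,0.0030300363
53.778693,0.19838873,0.045180992,0.15562676,0.84154357,0.0028296627
56.76186,0.19227687,0.041060028,0.13646291,0.86090211,0.0026349752
59.910505,0.18682345,0.037641971,0.11935777,0.87819473,0.0024475077
63.23381,0.18192366,0.034821425,0.10416775,0.89356386,0.0022683924
66.741463,0.17748855,0.032508623,0.090738693,0.9071629,0.0020984031
70.443689,0.17344271,0.030627072,0.078912756,0.91914924,0.0019380059
74.351282,0.16972224,0.029111559,0.068533816,0.92967877,0.0017874105
78.475633,0.16627305,0.027906449,0.059451415,0.93890197,0.0016466189
82.828767,0.16304943,0.026964245,0.051523477,0.94696105,0.0015154707
87.423375,0.16001281,0.026244369,0.044618001,0.95398832,0.001393683
92.27285,0.15713068,0.025712119,0.038613952,0.96010516,0.0012808836
97.391332,0.15437575,0.025337794,0.033401546,0.96542181,0.0011766396
102.79374,0.15172515,0.025095945,0.02888208,0.97003744,0.0010804803
108.49583,0.14915979,0.024964744,0.024967478,0.97404061,0.00099191528
114.51422,0.14666381,0.024925447,0.021579624,0.97750993,0.00091044826
120.86645,0.14422412,0.024961939,0.018649593,0.98051482,0.00083558811
127.57106,0.14182995,0.025060355,0.016116833,0.98311631,0.00076685649
134.64757,0.13947255,0.025208748,0.013928338,0.98536787,0.00070379341
142.11663,0.13714488,0.025396817,0.012037848,0.98731619,0.00064596092
150,0.13484132,0.025615673,0.01040509,0.98900196,0.00059294543
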