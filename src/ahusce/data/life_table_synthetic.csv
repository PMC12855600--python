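# SYNTHETIC period life table (NOT national statistics).
# Annual death probabilities from a Gompertz-Makeham hazard
# m(a) = A + B*exp(C*a), A=2.0e-4, B=1.15655e-5, C=0.105, with sex
# multipliers 1.30 (male) / 0.78 (female) on the hazard; calibrated so the
# sex-mixed (51% male) period life expectancy at birth is 81.0 years.
age,q_male,q_female
0,0.00027500,0.00016501
1,0.00027666,0.00016601
2,0.00027851,0.00016712
3,0.00028056,0.00016835
4,0.00028284,0.00016972
5,0.00028538,0.00017124
6,0.00028819,0.00017292
7,0.00029131,0.00017480
8,0.00029478,0.00017688
9,0.00029864,0.00017919
10,0.00030292,0.00018176
11,0.00030767,0.00018462
12,0.00031296,0.00018779
13,0.00031882,0.00019131
14,0.00032534,0.00019522
15,0.00033258,0.00019956
16,0.00034061,0.00020438
17,0.00034954,0.00020974
18,0.00035946,0.00021569
19,0.00037047,0.00022230
20,0.00038271,0.00022964
21,0.00039629,0.00023780
22,0.00041139,0.00024685
23,0.00042815,0.00025691
24,0.00044677,0.00026808
25,0.00046744,0.00028049
26,0.00049041,0.00029428
27,0.00051592,0.00030958
28,0.00054425,0.00032659
29,0.00057572,0.00034547
30,0.00061067,0.00036645
31,0.00064949,0.00038975
32,0.00069261,0.00041562
33,0.00074050,0.00044436
34,0.00079368,0.00047628
35,0.00085275,0.00051174
36,0.00091836,0.00055112
37,0.00099122,0.00059485
38,0.00107215,0.00064343
39,0.00116202,0.00069738
40,0.00126184,0.00075730
41,0.00137270,0.00082385
42,0.00149581,0.00089776
43,0.00163254,0.00097984
44,0.00178438,0.00107101
45,0.00195301,0.00117226
46,0.00214027,0.00128471
47,0.00234822,0.00140960
48,0.00257915,0.00154829
49,0.00283558,0.00170231
50,0.00312031,0.00187336
51,0.00343648,0.00206331
52,0.00378753,0.00227425
53,0.00417731,0.00250848
54,0.00461005,0.00276859
55,0.00509049,0.00305741
56,0.00562384,0.00337811
57,0.00621591,0.00373419
58,0.00687311,0.00412955
59,0.00760256,0.00456850
60,0.00841214,0.00505581
61,0.00931057,0.00559679
62,0.01030752,0.00619732
63,0.01141366,0.00686392
64,0.01264082,0.00760378
65,0.01400205,0.00842491
66,0.01551178,0.00933616
67,0.01718595,0.01034730
68,0.01904213,0.01146918
69,0.02109970,0.01271377
70,0.02338000,0.01409432
71,0.02590653,0.01562545
72,0.02870512,0.01732330
73,0.03180411,0.01920568
74,0.03523461,0.02129224
75,0.03903065,0.02360461
76,0.04322945,0.02616657
77,0.04787160,0.02900429
78,0.05300128,0.03214648
79,0.05866649,0.03562463
80,0.06491918,0.03947320
81,0.07181544,0.04372984
82,0.07941558,0.04843563
83,0.08778422,0.05363526
84,0.09699020,0.05937725
85,0.10710653,0.06571411
86,0.11821004,0.07270250
87,0.13038106,0.08040332
88,0.14370271,0.08888176
89,0.15826014,0.09820726
90,0.17413931,0.10845334
91,0.19142559,0.11969738
92,0.21020184,0.13202009
93,0.23054617,0.14550497
94,0.25252913,0.16023733
95,0.27621043,0.17630318
96,0.30163508,0.19378765
97,0.32882900,0.21277313
98,0.35779412,0.23333689
99,0.38850307,0.25554823
100,0.42089360,0.27946510
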