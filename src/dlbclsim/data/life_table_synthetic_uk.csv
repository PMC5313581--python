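age,sex,qx
0,male,0.0043
1,male,0.000205024
2,male,0.000207602
3,male,0.000210446
4,male,0.000213582
5,male,0.000217041
6,male,0.000220857
7,male,0.000225065
8,male,0.000229707
9,male,0.000234826
10,male,0.000240473
11,male,0.000246701
12,male,0.00025357
13,male,0.000261146
14,male,0.000269503
15,male,0.000278719
16,male,0.000288885
17,male,0.000300097
18,male,0.000312463
19,male,0.000326103
20,male,0.000341146
21,male,0.000357738
22,male,0.000376039
23,male,0.000396223
24,male,0.000418485
25,male,0.000443038
26,male,0.000470119
27,male,0.000499988
28,male,0.00053293
29,male,0.000569264
30,male,0.000609336
31,male,0.000653533
32,male,0.000702279
33,male,0.00075604
34,male,0.000815333
35,male,0.000880728
36,male,0.000952851
37,male,0.00103239
38,male,0.00112012
39,male,0.00121687
40,male,0.00132357
41,male,0.00144124
42,male,0.00157101
43,male,0.00171412
44,male,0.00187195
45,male,0.002046
46,male,0.00223793
47,male,0.00244958
48,male,0.00268297
49,male,0.00294033
50,male,0.00322411
51,male,0.00353701
52,male,0.00388202
53,male,0.00426242
54,male,0.00468181
55,male,0.00514417
56,male,0.0056539
57,male,0.0062158
58,male,0.0068352
59,male,0.00751792
60,male,0.00827039
61,male,0.00909967
62,male,0.0100135
63,male,0.0110205
64,male,0.01213
65,male,0.0133523
66,male,0.0146986
67,male,0.0161815
68,male,0.0178144
69,male,0.0196124
70,male,0.0215916
71,male,0.02377
72,male,0.0261671
73,male,0.0288041
74,male,0.0317044
75,male,0.0348932
76,male,0.0383983
77,male,0.0422494
78,male,0.0464792
79,male,0.0511228
80,male,0.0562183
81,male,0.0618068
82,male,0.0679323
83,male,0.0746421
84,male,0.0819867
85,male,0.09002
86,male,0.098799
87,male,0.108384
88,male,0.118837
89,male,0.130224
90,male,0.142614
91,male,0.156074
92,male,0.170676
93,male,0.186488
94,male,0.203579
95,male,0.222013
96,male,0.241851
97,male,0.263146
98,male,0.28594
99,male,0.310264
100,male,1
0,female,0.0036
1,female,0.000132155
2,female,0.000133474
3,female,0.000134937
4,female,0.000136558
5,female,0.000138355
6,female,0.000140347
7,female,0.000142556
8,female,0.000145004
9,female,0.000147717
10,female,0.000150725
11,female,0.000154059
12,female,0.000157755
13,female,0.000161851
14,female,0.000166393
15,female,0.000171426
16,female,0.000177006
17,female,0.000183192
18,female,0.000190048
19,female,0.000197648
20,female,0.000206073
21,female,0.000215411
22,female,0.000225763
23,female,0.000237237
24,female,0.000249956
25,female,0.000264055
26,female,0.000279683
27,female,0.000297007
28,female,0.000316209
29,female,0.000337495
30,female,0.000361089
31,female,0.000387243
32,female,0.000416233
33,female,0.000448367
34,female,0.000483986
35,female,0.000523468
36,female,0.000567232
37,female,0.000615742
38,female,0.000669512
39,female,0.000729111
40,female,0.000795173
41,female,0.000868397
42,female,0.000949559
43,female,0.00103952
44,female,0.00113923
45,female,0.00124974
46,female,0.00137224
47,female,0.001508
48,female,0.00165847
49,female,0.00182524
50,female,0.00201007
51,female,0.00221491
52,female,0.00244193
53,female,0.00269351
54,female,0.00297232
55,female,0.00328128
56,female,0.00362365
57,female,0.00400303
58,female,0.0044234
59,female,0.00488917
60,female,0.00540521
61,female,0.00597693
62,female,0.00661029
63,female,0.00731189
64,female,0.00808903
65,female,0.00894978
66,female,0.00990303
67,female,0.0109586
68,female,0.0121274
69,female,0.0134215
70,female,0.0148539
71,female,0.0164392
72,female,0.0181937
73,female,0.0201347
74,female,0.0222819
75,female,0.0246566
76,female,0.0272821
77,female,0.0301842
78,female,0.0333911
79,female,0.0369335
80,female,0.040845
81,female,0.0451624
82,female,0.0499254
83,female,0.0551774
84,female,0.0609653
85,female,0.0673397
86,female,0.0743552
87,female,0.0820701
88,female,0.0905468
89,female,0.0998518
90,female,0.110055
91,female,0.12123
92,female,0.133454
93,female,0.146805
94,female,0.161364
95,female,0.177213
96,female,0.194432
97,female,0.213097
98,female,0.233283
99,female,0.255055
100,female,1
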