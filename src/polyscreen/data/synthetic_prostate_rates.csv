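age,population,cancer_cases,cancer_deaths,all_cause_deaths
35,100000,13,3,48
36,100000,15,3,53
37,100000,17,3,59
38,100000,19,4,65
39,100000,21,4,71
40,100000,23,5,79
41,100000,26,5,87
42,100000,29,6,96
43,100000,32,6,106
44,100000,36,7,117
45,100000,40,8,129
46,100000,45,9,142
47,100000,50,10,157
48,100000,56,11,173
49,100000,62,12,191
50,100000,69,14,210
51,100000,78,16,232
52,100000,87,17,256
53,100000,97,19,283
54,100000,108,22,312
55,100000,120,24,344
56,100000,134,27,380
57,100000,150,30,419
58,100000,167,33,462
59,100000,187,37,510
60,100000,209,42,563
61,100000,233,47,621
62,100000,260,52,685
63,100000,290,58,756
64,100000,324,65,834
65,100000,362,72,920
66,100000,404,81,1016
67,100000,450,90,1121
68,100000,503,101,1237
69,100000,561,112,1365
70,100000,627,125,1506
71,100000,699,140,1662
72,100000,781,156,1834
73,100000,872,174,2024
74,100000,973,195,2234
75,100000,1086,217,2466
76,100000,1086,217,2696
77,100000,1086,217,2950
78,100000,1086,217,3230
79,100000,1086,217,3538
80,100000,1086,217,3878
81,100000,1086,217,4253
82,100000,1086,217,4666
83,100000,1086,217,5122
84,100000,1086,217,5624
85,100000,1086,217,6178
86,100000,1086,217,6789
87,100000,1086,217,7461
88,100000,1086,217,8203
89,100000,1086,217,9021
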