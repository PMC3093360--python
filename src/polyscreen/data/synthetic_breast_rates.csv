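age,population,cancer_cases,cancer_deaths,all_cause_deaths
25,100000,30,6,17
26,100000,33,7,19
27,100000,35,7,21
28,100000,38,8,23
29,100000,42,8,25
30,100000,45,9,28
31,100000,49,10,30
32,100000,53,11,33
33,100000,57,11,36
34,100000,62,12,40
35,100000,67,13,44
36,100000,73,15,48
37,100000,79,16,53
38,100000,85,17,58
39,100000,92,18,63
40,100000,100,20,69
41,100000,108,22,76
42,100000,117,23,84
43,100000,127,25,92
44,100000,138,28,101
45,100000,149,30,110
46,100000,162,32,121
47,100000,175,35,133
48,100000,190,38,146
49,100000,206,41,160
50,100000,223,45,176
51,100000,241,48,193
52,100000,261,52,211
53,100000,283,57,232
54,100000,307,61,255
55,100000,332,66,280
56,100000,332,66,302
57,100000,332,66,326
58,100000,332,66,352
59,100000,332,66,381
60,100000,332,66,414
61,100000,332,66,449
62,100000,332,66,488
63,100000,332,66,532
64,100000,332,66,579
65,100000,332,66,632
66,100000,332,66,690
67,100000,332,66,754
68,100000,332,66,824
69,100000,332,66,902
70,100000,332,66,987
71,100000,332,66,1081
72,100000,332,66,1185
73,100000,332,66,1300
74,100000,332,66,1426
75,100000,332,66,1565
76,100000,332,66,1719
77,100000,332,66,1888
78,100000,332,66,2075
79,100000,332,66,2280
80,100000,332,66,2507
81,100000,332,66,2757
82,100000,332,66,3033
83,100000,332,66,3336
84,100000,332,66,3671
85,100000,332,66,4040
86,100000,332,66,4447
87,100000,332,66,4896
88,100000,332,66,5391
89,100000,332,66,5936
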