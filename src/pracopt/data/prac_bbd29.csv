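run,ratio_mL_per_g,temperature_C,time_min,power_W,yield_pct
1,18,80,90,400,2.945
2,18,60,60,400,2.831
3,18,100,90,500,3.907
4,18,80,90,400,2.921
5,22,80,60,400,3.060
6,18,80,60,300,2.962
7,22,80,120,400,3.678
8,14,100,90,400,3.353
9,14,80,120,400,3.083
10,14,80,60,400,2.305
11,18,80,60,500,3.472
12,18,80,90,400,2.914
13,18,100,60,400,3.729
14,14,80,90,300,2.612
15,18,80,90,400,3.116
16,18,60,90,500,2.802
17,18,100,120,400,4.170
18,18,100,90,300,3.485
19,22,80,90,300,3.619
20,22,100,90,400,3.870
21,18,60,120,400,2.683
22,18,80,90,400,3.151
23,22,80,90,500,3.355
24,22,60,90,400,2.412
25,14,60,90,400,2.353
26,18,60,90,300,2.149
27,18,80,120,500,3.160
28,14,80,90,500,2.701
29,18,80,120,300,3.167
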