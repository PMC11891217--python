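run,pred_bbd,pred_bp,pred_gabp,pred_gaacobp
1,3.010,3.249,3.006,2.995
2,2.670,2.976,2.702,2.831
3,3.820,3.865,3.723,3.895
4,3.010,3.249,3.006,2.995
5,3.300,3.078,3.121,3.060
6,2.840,3.146,2.892,2.962
7,3.480,3.695,3.518,3.678
8,3.220,3.583,3.335,3.371
9,2.970,3.119,3.030,3.249
10,2.620,3.276,2.282,2.305
11,3.330,2.990,3.531,3.383
12,3.010,3.249,3.006,2.995
13,3.590,3.838,3.659,3.729
14,2.480,3.123,2.605,2.240
15,3.010,3.249,3.006,2.995
16,2.720,3.025,2.821,2.802
17,4.150,3.755,4.173,4.170
18,3.700,3.581,3.448,3.485
19,3.250,3.470,3.055,3.619
20,4.050,3.657,3.570,3.870
21,2.640,3.107,2.728,2.683
22,3.010,3.249,3.006,2.995
23,3.310,3.210,3.219,3.027
24,2.600,3.097,2.323,2.412
25,2.230,3.097,2.196,2.394
26,2.370,3.096,2.158,2.245
27,3.340,3.494,3.262,3.223
28,2.890,3.224,2.905,2.705
29,3.360,3.153,3.320,3.328
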