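batch,sbar_mu_hat,lambda_hat
1,0.7456,1.1896
2,0.9445,1.7504
3,0.6497,14.2823
4,0.6363,0.6088
5,0.6962,0.5533
6,0.9092,1.0856
7,0.8205,1.0194
8,0.7580,1.3304
9,0.5711,1.1599
10,0.7477,0.5552
11,0.6983,1.8897
12,0.7331,1.0680
13,0.5441,0.5153
14,0.7979,0.4903
15,0.2548,3.4421
16,0.5247,0.2333
17,0.1958,0.4072
18,0.6969,0.2390
19,0.5410,0.4283
20,0.2363,0.2409
21,0.5103,0.2364
22,0.1149,0.4908
23,0.6930,0.1623
24,0.4301,0.9075
25,0.5074,0.1809
26,0.7008,0.2447
27,0.5484,0.3720
28,0.6588,0.7616
29,0.6876,0.5021
30,0.2011,0.2430
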