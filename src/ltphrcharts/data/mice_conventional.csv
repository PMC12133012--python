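lifetime
0.0364
0.0381
0.0464
0.0564
0.1445
0.1482
0.1627
0.1718
0.1736
0.1800
0.1818
0.1873
0.1882
0.2000
0.2018
0.2073
0.2136
0.2227
0.2264
0.2273
0.2291
0.2327
0.2373
0.2409
0.2418
0.2545
0.2564
0.2882
0.2891
0.2945
0.3027
0.03100
0.3118
0.3236
0.3327
0.3482
0.3500
0.3627
0.3364
0.3700
0.3764
0.3818
0.3891
0.3918
0.3927
0.4009
0.4191
0.4200
0.4382
0.4500
0.4700
0.4700
0.4764
0.4773
0.4873
0.4991
0.5018
0.5036
0.5064
0.5073
0.5127
0.5155
0.5191
0.5327
0.5327
0.5400
0.5418
0.5500
0.5564
0.5627
0.5636
0.5645
0.5645
0.5655
0.5709
0.5736
0.5782
0.5845
0.5882
0.5882
0.5891
0.5900
0.5918
0.6009
0.6027
0.6055
0.6091
0.6236
0.6318
0.6336
0.6364
0.6409
0.6473
0.6482
0.6709
0.6800
0.6845
0.6918
0.6936
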