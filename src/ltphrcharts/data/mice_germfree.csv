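lifetime
0.1236
0.1436
0.1745
0.1754
0.1764
0.1773
0.1836
0.1927
0.1955
0.2082
0.2091
0.2155
0.2182
0.2218
0.2236
0.2245
0.2318
0.2355
0.2727
0.2736
0.2918
0.3064
0.3418
0.3773
0.3827
0.3909
0.3945
0.4036
0.4409
0.4509
0.4809
0.4882
0.5136
0.5364
0.5509
0.5600
0.5609
0.5672
0.5800
0.5927
0.5955
0.5955
0.5981
0.6000
0.6018
0.6136
0.6173
0.6191
0.6282
0.6300
0.6327
0.6427
0.6673
0.6691
0.6700
0.6791
0.6836
0.6881
0.6909
0.6991
0.7064
0.7003
0.7273
0.7273
0.7336
0.7464
0.7500
0.7773
0.7791
0.7855
0.7891
0.7909
0.7909
0.7936
0.8018
0.8136
0.8273
0.8491
0.8564
0.8964
0.9227
0.9264
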