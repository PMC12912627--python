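value
0.1292
0.3805
0.4049
0.2564
0.3091
0.2413
0.1390
0.1127
0.3547
0.3126
0.2991
0.2428
0.2942
0.0807
0.1285
0.2775
0.3311
0.2825
0.2559
0.2756
0.1652
0.1072
0.3383
0.3575
0.2708
0.2649
0.0961
0.1565
0.1580
0.1981
0.4154
0.3990
0.2483
0.1762
0.1760
0.1543
0.3238
0.3771
0.4132
0.4602
0.3523
0.1882
0.1742
0.4033
0.4999
0.3930
0.3963
0.3960
0.2029
0.1791
0.4768
0.5331
0.3739
0.4015
0.3828
0.1718
0.1657
0.4542
0.4772
0.3402
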