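value
0.3218
0.6820
0.7657
0.5782
0.7959
0.6182
0.5621
0.8581
0.5878
0.5941
0.9099
0.7279
0.8125
0.5014
0.5799
0.5461
0.5810
0.6239
0.6063
0.6523
0.7059
0.6646
0.8192
0.5217
0.7608
0.7194
0.8362
0.8889
0.9849
0.8456
0.8136
0.5706
0.8324
0.8606
0.5642
0.9033
0.5595
0.9665
0.5520
0.9089
0.9758
0.7918
0.6877
0.7045
0.5037
0.5316
0.6784
0.6171
0.5687
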