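hu,red
-1000,0.0
-120,0.8
0,1.0
36,1.06
480,1.456
900,1.60
1320,2.43
1380,3.73
1400,6.83
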