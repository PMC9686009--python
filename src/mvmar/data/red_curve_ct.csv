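hu,red
-1000,0.0
-200,0.8
0,1.0
60,1.06
800,1.456
1500,1.60
3000,2.43
3500,3.73
4000,6.83
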