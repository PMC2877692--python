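0.5504585701807927
0.12268390931624544
0.12268390931624545
0.06903860388823439
0.060395094982457986
0.06039509498245799
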