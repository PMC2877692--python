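0.0	1.0	1.0	5.656854249492381	6.4031242374328485	6.4031242374328485
1.0	0.0	1.4142135623730951	5.0	5.656854249492381	5.830951894845301
1.0	1.4142135623730951	0.0	5.0	5.830951894845301	5.656854249492381
5.656854249492381	5.0	5.0	0.0	1.0	1.0
6.4031242374328485	5.656854249492381	5.830951894845301	1.0	0.0	1.4142135623730951
6.4031242374328485	5.830951894845301	5.656854249492381	1.0	1.4142135623730951	0.0
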