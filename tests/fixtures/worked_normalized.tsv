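0.0	0.33349238479644694	0.33349238479644694	0.11662992126983605	0.09137227485672202	0.09137227485672202
0.33349238479644694	0.0	0.3108728863831917	0.14172109173939995	0.11863718681221057	0.11102964322034793
0.33349238479644694	0.3108728863831917	0.0	0.14172109173939995	0.11102964322034793	0.11863718681221057
0.11662992126983605	0.14172109173939995	0.14172109173939995	0.0	0.32373053598990514	0.32373053598990514
0.09137227485672202	0.11863718681221057	0.11102964322034793	0.32373053598990514	0.0	0.3306097856046276
0.09137227485672202	0.11102964322034793	0.11863718681221057	0.32373053598990514	0.3306097856046276	0.0
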