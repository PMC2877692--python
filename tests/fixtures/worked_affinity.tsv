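0.0	0.9674066137995398	0.9674066137995398	0.34632964643508046	0.25702249734765437	0.25702249734765437
0.9674066137995398	0.0	0.9358755564230921	0.4367433533406141	0.34632964643508046	0.3241214505632438
0.9674066137995398	0.9358755564230921	0.0	0.4367433533406141	0.3241214505632438	0.34632964643508046
0.34632964643508046	0.4367433533406141	0.4367433533406141	0.0	0.9674066137995398	0.9674066137995398
0.25702249734765437	0.34632964643508046	0.3241214505632438	0.9674066137995398	0.0	0.9358755564230921
0.25702249734765437	0.3241214505632438	0.34632964643508046	0.9674066137995398	0.9358755564230921	0.0
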