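t1	0.0	0.0
t2	1.0	0.0
t3	0.0	1.0
t4	4.0	4.0
t5	5.0	4.0
t6	4.0	5.0
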