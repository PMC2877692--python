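3.884476142518642
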