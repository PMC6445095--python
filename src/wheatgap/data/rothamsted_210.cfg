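name = rothamsted_210
total_awc_mm = 210
n_layers = 28
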