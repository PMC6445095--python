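name = lincoln_270
total_awc_mm = 270
n_layers = 36
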