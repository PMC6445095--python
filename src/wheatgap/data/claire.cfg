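name = Claire
P_h = 110.0
P_p = 0.565
G_f = 650.0
A_max = 0.007
S_G = 0.5
R_u = 3.0
W_ss = 1.27
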