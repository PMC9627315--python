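u_frac	v_frac
0.500	0.500
0.500	0.700
0.690	0.562
0.618	0.338
0.382	0.338
0.310	0.562
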