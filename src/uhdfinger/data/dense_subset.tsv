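u_frac	v_frac
0.370	0.370
0.500	0.370
0.630	0.370
0.370	0.500
0.500	0.500
0.630	0.500
0.370	0.630
0.500	0.630
0.630	0.630
0.290	0.290
0.710	0.710
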