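name	target	mono_delta	avg_delta
amidation	cterm	-0.98402	-0.9847
pyro_glu	nterm:Q	-17.02655	-17.0305
oxidation	M	15.99491	15.9994
dioxidation	M	31.98983	31.9988
carbamidomethyl	C	57.02146	57.0513
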