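enzyme	am_selectivity	ratio_maxdist_3.6	ratio_maxdist_3.8	ratio_maxdist_4.0
Round 1	0.45	0.34	0.29	0.25
Round 2	0.55	0.34	0.30	0.26
Round 8	0.76	0.35	0.33	0.30
aMOx	0.81	0.42	0.36	0.30
A275G	0.99	0.53	0.47	0.42
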