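residue	vdw	vdw_sd	ele	ele_sd	gb	gb_sd	np	np_sd	tot	tot_sd
279Ala	-0.75	0.27	-0.09	0.04	0.08	0.04	-0.11	0.02	-0.86	0.29
123Ile	-0.67	0.27	0.00	0.02	0.00	0.01	-0.11	0.02	-0.77	0.30
329Trp	-0.82	0.10	-0.05	0.01	0.23	0.02	-0.08	0.02	-0.72	0.08
97Leu	-0.52	0.09	0.00	0.01	0.04	0.01	-0.03	0.01	-0.52	0.10
278Val	-0.39	0.31	-0.04	0.03	-0.01	0.03	-0.02	0.02	-0.46	0.37
275Ala	-0.51	0.05	0.07	0.05	0.04	0.02	-0.04	0.01	-0.44	0.04
429Phe	-0.45	0.16	-0.02	0.03	0.10	0.05	-0.05	0.02	-0.42	0.15
211Trp	-0.51	0.22	-0.02	0.02	0.16	0.06	-0.04	0.02	-0.42	0.18
276Ile	-0.39	0.23	0.02	0.01	0.00	0.01	-0.03	0.04	-0.41	0.27
283Thr	-0.35	0.15	-0.04	0.03	0.09	0.07	-0.05	0.02	-0.35	0.15
All	-7.26	0.76	-0.25	0.08	1.20	0.12	-0.63	0.04	-6.94	0.70
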