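probe_id	gene	placement	island_status	mean_beta_smokers	mean_beta_nonsmokers	raw_p	corrected_p
cg19859270	GPR15	1stExon		0.77	0.87	2.44E-25	1.19E-19
cg05575921	AHRR	Body	N_Shore	0.68	0.83	2.54E-24	6.17E-19
cg08672695			N_Shelf	0.65	0.48	4.58E-20	7.40E-15
cg23576855	AHRR	Body	N_Shore	0.52	0.71	2.78E-17	3.37E-12
cg02657160	CPOX	Body	N_Shore	0.77	0.83	4.09E-17	3.97E-12
cg21161138	AHRR	Body		0.62	0.70	5.74E-17	4.64E-12
cg18230367	RNASE4	TSS200	N_Shore	0.05	0.07	2.13E-16	1.48E-11
cg02319016	PAK2	5'UTR	S_Shelf	0.70	0.56	1.53E-15	9.27E-11
cg26607002	NOSTRIN	TSS200		0.68	0.63	4.31E-15	2.32E-10
cg04677326	C19orf28	TSS200	Island	0.17	0.15	4.98E-15	2.42E-10
cg01940273			Island	0.50	0.59	5.69E-15	2.51E-10
cg05457881	C6orf218	TSS1500		0.18	0.22	6.91E-15	2.79E-10
cg06126421				0.65	0.76	7.79E-15	2.91E-10
cg21566642			Island	0.38	0.48	8.62E-15	2.99E-10
cg13086586	PAICS	Body	S_Shore	0.17	0.23	3.26E-14	1.05E-09
cg15281724	TXLNB	Body		0.78	0.69	9.63E-14	2.92E-09
cg15645254	NAALAD2	Body		0.78	0.75	1.23E-13	3.51E-09
cg19111030	ANKRD53	TSS1500	N_Shore	0.17	0.20	1.96E-13	5.30E-09
cg09741592	HNRNPA1	Body	S_Shore	0.18	0.23	3.23E-13	8.25E-09
cg08528204	TMEM116	TSS1500	S_Shore	0.17	0.20	8.77E-13	2.07E-08
cg17391741			N_Shore	0.82	0.85	8.97E-13	2.07E-08
cg15614155			N_Shore	0.83	0.78	1.06E-12	2.34E-08
cg05916255	ABCC2	Body	N_Shore	0.85	0.82	1.17E-12	2.47E-08
cg25223391	UVRAG	Body		0.71	0.67	1.31E-12	2.52E-08
cg00736283	ASF1B	TSS200	Island	0.13	0.11	1.32E-12	2.52E-08
cg26703534	AHRR	Body	S_Shelf	0.62	0.68	1.35E-12	2.52E-08
cg16851858			N_Shelf	0.73	0.77	1.55E-12	2.80E-08
cg02521854			N_Shelf	0.13	0.11	1.69E-12	2.93E-08
cg15658543	CARD11	5'UTR		0.88	0.85	1.91E-12	3.20E-08
cg13789443	GALNT11	5'UTR	S_Shore	0.60	0.55	2.00E-12	3.24E-08
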