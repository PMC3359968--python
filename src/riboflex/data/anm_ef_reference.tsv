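protein	tth_ef	tth_p	eco_ef	eco_p
S02	0.97	0.505	1.05	0.352
S03	2.22	0.001	2.07	<0.001
S04	1.39	0.013	1.44	0.005
S05	1.78	0.004	1.62	0.012
S06	0.83	0.452	1.11	0.278
S07	2.76	<0.001	1.85	0.041
S08	1.35	0.074	1.27	0.108
S09	2.15	<0.001	1.73	<0.001
S10	1.40	0.010	1.73	<0.001
S11	1.69	0.008	3.20	<0.001
S12	1.58	0.001	1.40	0.007
S13	1.43	0.002	1.48	<0.001
S14	1.55	0.017	1.10	0.179
S15	1.36	0.005	1.23	0.038
S16	1.67	0.004	1.02	0.428
S17	1.48	0.005	1.33	0.063
S18	0.58	0.936	0.93	0.585
S19	1.09	0.125	0.88	0.166
S20	1.33	0.031	1.24	0.063
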