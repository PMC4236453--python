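tf_a	tf_b	theta	se	pvalue
AsnC	Trh2	0.47	0.16	3.3e-3
AsnC	Trh3	0.64	0.11	4.1e-9
AsnC	Trh4	0.33	0.09	4.6e-4
AsnC	Trh6	0.54	0.13	3.2e-5
AsnC	Trh7	0.51	0.11	4.4e-6
AsnC	VNG1179C	0.57	0.19	3.3e-3
AsnC	VNG1237C	0.42	0.16	7.6e-3
Trh2	Trh3	0.60	0.09	2.7e-11
Trh2	Trh4	0.64	0.09	7.1e-13
Trh2	Trh6	0.44	0.10	3.3e-5
Trh2	Trh7	0.66	0.09	2.2e-14
Trh2	VNG1179C	0.48	0.11	3.8e-5
Trh2	VNG1237C	0.40	0.11	5.5e-4
Trh3	Trh4	0.50	0.06	1.5e-15
Trh3	Trh6	0.58	0.08	2.8e-11
Trh3	Trh7	0.73	0.07	2.6e-23
Trh3	VNG1179C	0.57	0.09	9.3e-11
Trh3	VNG1237C	0.65	0.08	6.8e-14
Trh4	Trh6	0.44	0.07	1.4e-10
Trh4	Trh7	0.72	0.07	1.4e-24
Trh4	VNG1179C	0.79	0.08	6.5e-24
Trh4	VNG1237C	0.44	0.08	1.5e-8
Trh6	Trh7	0.83	0.08	4.1e-23
Trh6	VNG1179C	0.49	0.12	4.7e-5
Trh6	VNG1237C	0.60	0.11	2.5e-7
Trh7	VNG1179C	0.87	0.08	6.0e-24
Trh7	VNG1237C	0.87	0.08	3.9e-24
VNG1179C	VNG1237C	0.60	0.10	2.0e-9
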