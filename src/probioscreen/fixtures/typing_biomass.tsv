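isolate_id	species	biomass_g_per_L	biomass_se	rapd_pattern	selected
C47	Candida haemuloni	0.69	0.13	A	1
C45	Candida haemuloni	0.57	0.07	A	0
C44	Candida haemuloni	2.14	0.17	B	0
C01	Candida haemuloni	2.00	0.07	B	1
C13	Candida haemuloni	1.94	0.05	B	0
C29	Candida haemuloni	1.89	0.06	B	0
C37	Candida haemuloni	1.86	0.08	B	0
C22	Candida haemuloni	1.84	0.10	B	0
C42	Candida haemuloni	1.65	0.03	B	0
C27	Candida haemuloni	1.72	0.01	C	1
C33	Candida parapsilosis	0.83	0.09	D	1
C46	Candida parapsilosis	1.57	0.02	E	1
C50	Candida parapsilosis	1.53	0.04	E	0
C31	Candida parapsilosis	1.50	0.04	F	1
C32	Candida parapsilosis	1.36	0.07	G	1
C36	Candida parapsilosis	1.59	0.04	H	1
C28	Debaryomyces hansenii	1.05	0.06	I	1
C40	Debaryomyces hansenii	0.93	0.09	J	1
C19	Debaryomyces hansenii	0.88	0.06	J	0
C03	Debaryomyces hansenii	1.00	0.15	K	1
C21	Debaryomyces hansenii	0.86	0.08	K	0
C49	Debaryomyces hansenii	0.78	0.07	K	0
C62	Debaryomyces hansenii	0.07	0.01	K	0
C38	Debaryomyces hansenii	0.98	0.13	L	0
C17	Debaryomyces hansenii	0.89	0.04	L	1
C24	Debaryomyces hansenii	0.88	0.05	L	0
C30	Debaryomyces hansenii	0.87	0.08	L	0
C25	Debaryomyces hansenii	0.86	0.02	L	0
C16	Debaryomyces hansenii	0.83	0.08	L	0
C41	Debaryomyces hansenii	0.70	0.12	L	0
C10	Debaryomyces hansenii	1.02	0.08	M	1
C65	Debaryomyces hansenii	0.95	0.06	M	0
C12	Debaryomyces hansenii	0.94	0.09	M	0
C43	Debaryomyces hansenii	0.93	0.04	M	0
C60	Debaryomyces hansenii	0.91	0.07	M	0
C26	Debaryomyces sp.	0.87	0.06	N	1
C04	Debaryomyces sp.	0.50	0.04	N	0
C67	Debaryomyces sp.	0.30	0.07	O	1
C61	Naganishia sp.	0.66	0.02	P	1
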