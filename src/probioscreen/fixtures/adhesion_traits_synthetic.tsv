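strain_id	species	hemolysis	halo_mm	biofilm_od	autoaggregation_1h_pct	autoaggregation_24h_pct	hydrophobicity_xylene_pct	hydrophobicity_ethyl_acetate_pct	hydrophobicity_chloroform_pct
C01	Candida haemuloni	gamma	0	1.32	12.4	84.1	78.20	41.2	88.6
C27	Candida haemuloni	gamma	0	1.18	15.8	86.3	64.70	35.4	90.2
C47	Candida haemuloni	gamma	0	0.41	28.6	81.5	55.10	44.8	84.7
C31	Candida parapsilosis	gamma	0	1.54	34.2	88.9	52.30	60.26	79.3
C32	Candida parapsilosis	gamma	0	1.47	14.1	85.2	48.90	52.7	82.1
C33	Candida parapsilosis	gamma	0	1.21	31.7	83.6	45.60	38.9	80.8
C36	Candida parapsilosis	gamma	0	1.63	38.5	87.4	16.50	25.3	74.53
C46	Candida parapsilosis	gamma	0	1.58	36.9	89.7	16.20	22.1	76.9
C03	Debaryomyces hansenii	gamma	0	0.33	11.2	82.8	58.40	33.6	91.5
C10	Debaryomyces hansenii	gamma	0	0.47	29.8	90.2	61.80	30.9	94.39
C17	Debaryomyces hansenii	gamma	0	0.28	9.6	80.9	49.70	28.4	87.2
C28	Debaryomyces hansenii	gamma	0	0.39	13.5	83.9	56.20	26.7	92.8
C40	Debaryomyces hansenii	gamma	0	0.31	26.4	82.2	44.30	31.5	86.4
C26	Debaryomyces sp.	gamma	0	0.36	10.8	79.4	42.90	24.6	83.9
C67	Debaryomyces sp.	gamma	0	1.09	12.9	80.3	30.68	18.98	81.6
C61	Naganishia sp.	gamma	0	0.44	27.3	78.6	40.50	36.2	85.3
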