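strain_id	species	biomass	enzymes	hemolysis_observed	antagonism	biofilm	autoaggregation	hydrophobicity	total	selected
C01	Candida haemuloni	1	0	0	0	1	0	1	3	1
C27	Candida haemuloni	1	1	0	0	1	0	1	4	1
C47	Candida haemuloni	0	0	0	0	0	1	1	2	0
C31	Candida parapsilosis	1	1	0	0	1	1	1	5	1
C32	Candida parapsilosis	1	1	0	0	1	0	1	4	1
C33	Candida parapsilosis	0	0	0	0	1	1	1	3	0
C36	Candida parapsilosis	1	1	0	0	1	1	0	4	0
C46	Candida parapsilosis	1	1	0	0	1	1	0	4	1
C03	Debaryomyces hansenii	1	0	0	0	0	0	1	2	0
C10	Debaryomyces hansenii	1	1	0	0	0	1	1	4	1
C17	Debaryomyces hansenii	0	0	0	0	0	0	1	1	0
C28	Debaryomyces hansenii	1	1	0	0	0	0	1	3	1
C40	Debaryomyces hansenii	0	0	0	0	0	1	1	2	0
C26	Debaryomyces sp.	0	0	0	0	0	0	1	1	0
C67	Debaryomyces sp.	0	0	0	0	1	0	1	2	0
C61	Naganishia sp.	0	0	0	0	0	1	1	2	0
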