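isolate_id	fish_id	origin	feed	species_sequence	phylum	species_specific_pcr	accession
C29	FC2	EMAGROCOM	FFP	Candida haemuloni	Ascomycota		OQ184038
C31	FC2	EMAGROCOM	FFP	Candida parapsilosis	Ascomycota		OQ184039
C47	FC4	EMAGROCOM	FFP	Candida haemuloni	Ascomycota		OQ184040
C32	FC6	EMAGROCOM	FFP	Candida parapsilosis	Ascomycota		OQ184041
C36	FC6	EMAGROCOM	FFP	Candida parapsilosis	Ascomycota		OQ184042
C46	FC6	EMAGROCOM	FFP	Candida parapsilosis	Ascomycota		OQ184043
C50	FC6	EMAGROCOM	FFP	Candida parapsilosis	Ascomycota		OQ184044
C62	FC3	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184045
C27	FC5	EMAGROCOM	FFP	Candida haemuloni	Ascomycota		OQ184046
C24	FC5	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184047
C28	FC5	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184048
C37	FC1	EMAGROCOM	FFP	Candida haemuloni	Ascomycota		OQ184049
C33	FC1	EMAGROCOM	FFP	Candida parapsilosis	Ascomycota		OQ184050
C25	FC1	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184051
C30	FC1	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184052
C38	FC1	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184053
C26	FC1	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota		OQ184054
C67	FC1	EMAGROCOM	FFP	Debaryomyces sp.	Ascomycota		OQ184055
C61	FC1	EMAGROCOM	FFP	Naganishia sp.	Basidiomycota		OQ184056
C13	FC32	CENAIM	FFP	Candida haemuloni	Ascomycota		OQ184057
C16	FC32	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184058
C17	FC32	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184059
C01	FC34	CENAIM	FFP	Candida haemuloni	Ascomycota		OQ184060
C03	FC20	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184061
C40	FC20	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184062
C41	FC20	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184063
C04	FC20	CENAIM	FFP	Debaryomyces sp.	Ascomycota		OQ184064
C44	FC23	CENAIM	FFP	Candida haemuloni	Ascomycota		OQ184065
C45	FC23	CENAIM	FFP	Candida haemuloni	Ascomycota		OQ184066
C10	FC23	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184067
C21	FC24	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184068
C43	FC25	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184069
C65	FC25	CENAIM	FFP	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184070
C19	FC28	CENAIM	FF	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184071
C22	FC27	CENAIM	FF	Candida haemuloni	Ascomycota		OQ184072
C42	FC27	CENAIM	FF	Candida haemuloni	Ascomycota		OQ184073
C12	FC27	CENAIM	FF	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184074
C60	FC27	CENAIM	FF	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184075
C49	FC30	CENAIM	FF	Debaryomyces sp.	Ascomycota	Debaryomyces hansenii	OQ184076
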