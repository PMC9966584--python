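enzyme	C01	C27	C47	C31	C32	C33	C36	C46	C03	C10	C17	C28	C40	C26	C67	C61
Alkaline phosphatase	neg	neg	neg	med	med	neg	med	med	med	med	med	med	neg	neg	neg	neg
Esterase (C4)	pos	med	med	med	med	med	med	pos	med	med	med	med	med	med	med	med
Esterase lipase (C8)	pos	med	med	med	med	med	med	med	med	med	med	med	med	med	med	med
Lipase (C14)	neg	med	neg	neg	neg	neg	neg	neg	neg	med	neg	med	neg	neg	neg	neg
Leucine arylamidase	pos	pos	pos	pos	pos	pos	pos	pos	med	med	pos	pos	pos	pos	pos	pos
Valine arylamidase	pos	pos	med	pos	pos	med	pos	pos	med	med	med	med	med	med	med	med
Cystine arylamidase	med	med	neg	med	med	neg	neg	med	neg	neg	neg	neg	neg	neg	neg	neg
Trypsin	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
Alpha-chymotrypsin	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
Acid phosphatase	neg	med	pos	pos	pos	med	pos	pos	neg	med	med	med	med	med	med	pos
Naphthol-AS-BI-phosphohydrolase	neg	med	med	med	pos	med	pos	pos	neg	med	med	med	med	med	med	med
Alpha-galactosidase	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
Beta-galactosidase	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
Beta-glucuronidase	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
Alpha-glucosidase	neg	neg	neg	med	med	med	med	pos	neg	med	neg	neg	neg	neg	neg	neg
Beta-glucosidase	neg	neg	pos	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	pos
N-acetyl-beta-glucosaminidase	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
Alpha-mannosidase	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
Alpha-fucosidase	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg	neg
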