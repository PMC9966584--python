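group	replicate	hour	alive	n0
control	1	0	100	100
control	2	0	100	100
control	3	0	100	100
control	1	24	36	100
control	2	24	33	100
control	3	24	33	100
C01	1	0	100	100
C01	2	0	100	100
C01	3	0	100	100
C01	1	24	35	100
C01	2	24	35	100
C01	3	24	31	100
C27	1	0	100	100
C27	2	0	100	100
C27	3	0	100	100
C27	1	24	38	100
C27	2	24	31	100
C27	3	24	35	100
C31	1	0	100	100
C31	2	0	100	100
C31	3	0	100	100
C31	1	24	33	100
C31	2	24	36	100
C31	3	24	30	100
C32	1	0	100	100
C32	2	0	100	100
C32	3	0	100	100
C32	1	24	12	100
C32	2	24	9	100
C32	3	24	15	100
C46	1	0	100	100
C46	2	0	100	100
C46	3	0	100	100
C46	1	24	32	100
C46	2	24	36	100
C46	3	24	34	100
C10	1	0	100	100
C10	2	0	100	100
C10	3	0	100	100
C10	1	24	54	100
C10	2	24	47	100
C10	3	24	61	100
C28	1	0	100	100
C28	2	0	100	100
C28	3	0	100	100
C28	1	24	35	100
C28	2	24	30	100
C28	3	24	37	100
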