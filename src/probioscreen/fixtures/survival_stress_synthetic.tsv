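group	replicate	hour	alive	n0
control	1	0	10	10
control	2	0	10	10
control	3	0	10	10
control	1	8	7	10
control	2	8	8	10
control	3	8	7	10
C01	1	0	10	10
C01	2	0	10	10
C01	3	0	10	10
C01	1	8	2	10
C01	2	8	3	10
C01	3	8	2	10
C27	1	0	10	10
C27	2	0	10	10
C27	3	0	10	10
C27	1	8	7	10
C27	2	8	7	10
C27	3	8	8	10
C31	1	0	10	10
C31	2	0	10	10
C31	3	0	10	10
C31	1	8	3	10
C31	2	8	2	10
C31	3	8	2	10
C32	1	0	10	10
C32	2	0	10	10
C32	3	0	10	10
C32	1	8	6	10
C32	2	8	8	10
C32	3	8	7	10
C46	1	0	10	10
C46	2	0	10	10
C46	3	0	10	10
C46	1	8	2	10
C46	2	8	2	10
C46	3	8	3	10
C10	1	0	10	10
C10	2	0	10	10
C10	3	0	10	10
C10	1	8	8	10
C10	2	8	7	10
C10	3	8	7	10
C28	1	0	10	10
C28	2	0	10	10
C28	3	0	10	10
C28	1	8	7	10
C28	2	8	6	10
C28	3	8	8	10
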