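strain	condition	assay	mean	sd	n	significant
control	untreated	NR	2.6	0.3	3	False
control	untreated	G6PDH	8.0	1	3	False
control	untreated	GR	3.8	0.5	3	False
control	untreated	GPx	0.40	0.04	3	False
control	untreated	catalase	0.20	0.02	3	False
control	untreated	sterol	5.8	0.6	3	False
control	MSB	NR	1.6	0.3	3	True
control	MSB	G6PDH	8.5	1	3	False
control	MSB	GR	4.8	0.6	3	True
control	MSB	GPx	0.51	0.05	3	True
control	MSB	catalase	0.38	0.03	3	True
control	MSB	sterol	5.7	0.2	3	False
control	tBOOH	NR	0.3	0.1	3	True
control	tBOOH	G6PDH	8.3	0.9	3	False
control	tBOOH	GR	4.4	0.6	3	True
control	tBOOH	GPx	0.57	0.05	3	True
control	tBOOH	catalase	0.40	0.03	3	True
control	tBOOH	sterol	3.3	0.2	3	True
control	diamide	NR	0.6	0.1	3	True
control	diamide	G6PDH	7.8	1	3	False
control	diamide	GR	4.5	0.5	3	True
control	diamide	GPx	0.77	0.08	3	True
control	diamide	catalase	0.30	0.03	3	True
control	diamide	sterol	7.0	0.7	3	False
atfa	untreated	NR	2.8	0.3	3	False
atfa	untreated	G6PDH	7.4	0.9	3	False
atfa	untreated	GR	3.4	0.4	3	False
atfa	untreated	GPx	0.33	0.04	3	False
atfa	untreated	catalase	0.18	0.02	3	False
atfa	untreated	sterol	6.8	0.7	3	False
atfa	MSB	NR	3.1	0.4	3	True
atfa	MSB	G6PDH	8.0	1	3	False
atfa	MSB	GR	4.6	0.5	3	True
atfa	MSB	GPx	0.46	0.05	3	True
atfa	MSB	catalase	0.43	0.04	3	True
atfa	MSB	sterol	5.7	0.4	3	False
atfa	tBOOH	NR	0.3	0.1	3	True
atfa	tBOOH	G6PDH	7.7	0.8	3	False
atfa	tBOOH	GR	4.8	0.5	3	True
atfa	tBOOH	GPx	0.58	0.06	3	True
atfa	tBOOH	catalase	0.44	0.04	3	True
atfa	tBOOH	sterol	2.7	0.2	3	True
atfa	diamide	NR	0.7	0.1	3	True
atfa	diamide	G6PDH	8.1	1.2	3	False
atfa	diamide	GR	4.6	0.4	3	True
atfa	diamide	GPx	0.44	0.05	3	True
atfa	diamide	catalase	0.43	0.04	3	True
atfa	diamide	sterol	7.3	0.3	3	False
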