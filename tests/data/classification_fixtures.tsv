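gene	cdna	expected_class	contributors	ptc	control_af	patient_af	missense_score	splice_delta	minigene_result	segregation_consistent	genotype_context	quantitative_synthetic
GPR98	c.8992_8994delinsAAGTTCC	Pathogenic	a	1	.	.	.	.	.	.	.	0
USH2A	c.14475_14484del	Pathogenic	g,a	1	.	.	.	.	.	yes	.	0
USH2A	c.14766delG	Pathogenic	g,a	1	.	.	.	.	.	yes	.	0
CDH23	c.5015_5016delAT	Pathogenic	a	1	.	.	.	.	.	.	.	0
USH2A	c.2882delA	Pathogenic	a	1	.	.	.	.	.	.	.	0
GPR98	c.2864C>A	Pathogenic	a	1	.	.	.	.	.	.	.	0
MYO7A	c.5502G>A	Pathogenic	a	1	.	.	.	.	.	.	.	0
GPR98	c.7129C>T	Pathogenic	a	1	.	.	.	.	.	.	.	0
GPR98	c.13536_13537delTC	Pathogenic	a	1	.	.	.	.	.	.	.	0
USH1C	c.496+1C>T	Pathogenic	a	1	.	.	.	.	.	.	.	0
TMC1	c.1165C>T	Pathogenic	a	1	.	.	.	.	.	.	.	0
GJB2	c.35delG	Pathogenic	a	1	.	.	.	.	.	.	.	0
OTOF	c.1392+1G>T	Pathogenic	a	1	.	.	.	.	.	.	.	0
CDH23	c.9278+5G>C	UV4	f	.	.	.	.	.	deleterious	.	.	0
PDZD7	c.1011C>T	Neutral	b,e	.	0.03	.	.	0.1	.	.	.	0
CLRN1	c.472+4C>T	Neutral	b	.	0.05	.	.	.	.	.	.	0
MYO15A	c.3413A>G	Neutral	b	.	0.04	.	.	.	.	.	.	0
CDH23	c.6829+1G>A	UV4	e	.	.	.	.	0.9	.	.	.	1
USH1C	c.307C>T	UV3	d	.	.	.	0.9	.	.	.	.	1
CDH23	c.9904G>A	UV3	d	.	0.001	.	0.92	.	.	.	.	1
GPR98	c.10820T>C	UV3	d	.	.	.	0.85	.	.	.	.	1
MYO7A	c.472G>A	UV3	d	.	.	.	0.88	.	.	.	.	1
MYO7A	c.6220C>T	UV2	d	.	.	.	0.6	.	.	.	.	1
GPR98	c.2727C>A	UV2	e	.	.	.	.	0.65	.	.	.	1
DFNB31	c.1204-17A>G	UV2	e	.	.	.	.	0.6	.	.	.	1
MYO15A	c.7468G>A	UV1	b	.	0.005	.	0.2	.	.	.	.	1
USH2A	c.14662A>T	UV1	d	.	0.004	.	0.3	.	.	.	.	1
MYO15A	c.54G>A	UV1	b,e	.	0.006	.	.	0.15	.	.	.	1
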