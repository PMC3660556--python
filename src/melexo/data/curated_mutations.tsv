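sample_id	gene_id	n_ns	truncating	homozygous	compound_loss
Me01	PIK3R4	1	0	0	0
Me02	PIK3C2G	2	1	0	0
Me04	PIK3C2G	1	0	0	0
Me04	PREX2	2	0	0	0
Me08	PIK3CG	1	0	0	0
Me08	PREX2	3	0	0	0
Me01	MAP3K4	1	0	0	0
Me01	BRAF	1	0	0	0
Me04	BRAF	1	0	1	0
Me05	MAPK6	1	0	0	0
Me08	MAP2K3	1	0	0	0
Me08	BRAF	1	0	0	0
Me12	MAP3K5	1	0	0	0
Me12	BRAF	1	0	0	0
Me01	GRIN2B	1	0	0	0
Me01	GRIN3A	1	0	0	0
Me01	GRM5	1	0	0	0
Me01	PLCB1	1	0	0	0
Me01	PLCB4	1	0	0	0
Me01	PLCE1	1	0	0	0
Me01	PLCZ1	1	0	0	0
Me02	GRIN3A	1	0	0	0
Me04	GRM1	1	0	0	0
Me04	PLCXD2	1	0	0	0
Me02	NRAS	1	0	1	0
Me01	FGFR1	1	0	0	0
Me02	MET	1	0	0	0
Me04	PTK2B	1	0	0	0
Me05	PTK7	1	0	0	0
Me01	ADAM22	1	0	0	1
Me01	ADAMTS18	1	0	0	0
Me01	MMP24	1	0	0	0
Me01	MMP25	1	0	0	0
Me02	ADAMTS9	1	0	0	0
Me04	ADAMTS12	1	1	0	0
Me08	ADAM23	1	0	0	0
Me08	ADAMTS6	1	0	0	0
Me08	ADAMTS9	1	0	0	0
Me08	MMP19	1	0	0	0
Me01	PTPN1	1	0	0	0
Me01	PTPRK	1	0	0	0
Me02	PTPN13	1	0	0	0
Me04	PTPN13	1	0	0	0
Me04	PTPRF	1	0	1	0
Me05	PTPRD	1	0	0	1
Me12	PTPLA	1	0	1	0
Me01	GPR64	1	0	0	0
Me01	GPR101	1	0	1	0
Me01	GPR112	1	0	1	0
Me01	GPR158	1	0	0	0
Me02	GPR113	1	0	1	0
Me04	GPR151	1	1	1	0
Me05	GPR112	1	0	1	0
Me05	GPR113	1	0	0	0
Me05	GPR133	1	0	0	0
Me08	GPR158	1	0	0	0
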