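sample_id	gene_id	event	truncating	homozygous	source_label
Me01	BRAF	mutation	0	0	malignant melanoma
Me01	HYDIN	mutation	0	0	other tumor types
Me01	SPTA1	mutation	0	0	other tumor types
Me01	XKR6	mutation	1	0	malignant melanoma
Me02	NRAS	mutation	0	1	malignant melanoma
Me02	SMC1B	mutation	0	0	other tumor types
Me04	BRAF	mutation	0	1	malignant melanoma
Me04	MADD	mutation	0	0	malignant melanoma
Me04	SPTA1	mutation	0	0	other tumor types
Me05	MKS1	mutation	0	0	other tumor types
Me08	BRAF	mutation	0	0	malignant melanoma
Me08	PKHD1	mutation	0	0	malignant melanoma
Me12	BRAF	mutation	0	0	malignant melanoma
Me01	CDKN2A	deletion	0	1	melanoma
Me02	CDKN2A	deletion	0	1	melanoma
Me02	MAP2K4	deletion	0	0	ovary, lung, breast
Me05	AXIN1	deletion	0	0	stomach, liver
Me05	CDKN2A	deletion	0	0	melanoma
Me05	JAK2	deletion	0	0	hematopoietic
Me05	KIT	deletion	0	0	GIST, hematopoietic
Me05	PDGFRA	deletion	0	0	GIST
Me05	RB1	deletion	0	0	brain, lung
Me05	TET2	deletion	0	0	hematopoietic
Me05	ZRANB1	deletion	0	0	ovary
Me08	APC	deletion	0	0	many tumor types
Me08	MAP2K4	deletion	0	0	ovary, lung, breast
Me12	CDKN2A	deletion	0	1	melanoma
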