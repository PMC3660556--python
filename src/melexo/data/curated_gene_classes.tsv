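gene_id	class_tags
PIK3R4	PI3K/Akt signalling
PIK3C2G	PI3K/Akt signalling
PREX2	PI3K/Akt signalling
PIK3CG	PI3K/Akt signalling
MAP3K4	MAPK signalling
BRAF	MAPK signalling;RAS-RAF Ser/Thr kinases
MAPK6	MAPK signalling
MAP2K3	MAPK signalling
MAP3K5	MAPK signalling
GRIN2B	Glutamate signalling
GRIN3A	Glutamate signalling
GRM5	Glutamate signalling;G protein-coupled receptors
PLCB1	Glutamate signalling
PLCB4	Glutamate signalling
PLCE1	Glutamate signalling
PLCZ1	Glutamate signalling
GRM1	Glutamate signalling;G protein-coupled receptors
PLCXD2	Glutamate signalling
NRAS	RAS-RAF Ser/Thr kinases
FGFR1	Protein tyrosine kinases
MET	Protein tyrosine kinases
PTK2B	Protein tyrosine kinases
PTK7	Protein tyrosine kinases
ADAM22	Metalloproteinases
ADAMTS18	Metalloproteinases
MMP24	Metalloproteinases
MMP25	Metalloproteinases
ADAMTS9	Metalloproteinases
ADAMTS12	Metalloproteinases
ADAM23	Metalloproteinases
ADAMTS6	Metalloproteinases
MMP19	Metalloproteinases
PTPN1	Protein tyrosine phosphatases
PTPRK	Protein tyrosine phosphatases
PTPN13	Protein tyrosine phosphatases
PTPRF	Protein tyrosine phosphatases
PTPRD	Protein tyrosine phosphatases
PTPLA	Protein tyrosine phosphatases
GPR64	G protein-coupled receptors
GPR101	G protein-coupled receptors
GPR112	G protein-coupled receptors
GPR158	G protein-coupled receptors
GPR113	G protein-coupled receptors
GPR151	G protein-coupled receptors
GPR133	G protein-coupled receptors
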