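class_name	kind	n_ns	n_s
PI3K/Akt signalling	signalling cascade	10	1
MAPK signalling	signalling cascade	8	3
Glutamate signalling	signalling cascade	10	13
RAS-RAF Ser/Thr kinases	molecular function	5	0
Protein tyrosine kinases	molecular function	4	2
Metalloproteinases	molecular function	10	7
Protein tyrosine phosphatases	molecular function	7	3
G protein-coupled receptors	molecular function	12	5
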