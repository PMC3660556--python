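gene_id	mutated_samples	n_ns_mutations
C4orf23	Me04,Me05	2
PAICS	Me01,Me02	2
CNST	Me01,Me12	2
KIF23	Me01,Me08	2
MRPL1	Me01,Me08	2
MUC19	Me01,Me08	2
DCAKD	Me01,Me04	2
MRPL53	Me01,Me04	2
RBMXL1	Me01,Me04	4
ZNF66P	Me01,Me04,Me05	3
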