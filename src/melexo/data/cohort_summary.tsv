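sample_id	n_total_snvs	n_novel	n_novel_coding	n_nonsynonymous	n_synonymous
Me01	128827	11126	2791	659	333
Me02	131830	8360	1626	385	178
Me04	159708	10230	1733	370	228
Me05	128087	6001	1117	189	94
Me08	161058	9534	1697	369	194
Me12	161721	7869	1224	200	126
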