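# Two-locus haplotype frequencies (rs7909153 allele, rs17112895 allele) per population
# haplotype classes: dd = derived-derived (A,T), da = derived-ancestral (A,C),
# ad = ancestral-derived (G,T), aa = ancestral-ancestral (G,C)
population	dd	da	ad	aa
Gumuz	0.71	0	0	0.29
Amhara	0.21	0.02	0	0.77
YRI	0.16	0.03	0.01	0.8
LWK	0.04	0.19	0.13	0.64
MSL	0.13	0.03	0.01	0.84
CEU	0	0	0	1
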