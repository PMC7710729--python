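# Gumuz genotype fractions at the two TRPP3 non-synonymous substitutions
# columns: variant_id, position_hg19, ancestral, derived, frac_ancestral_hom, frac_het, frac_derived_hom
variant_id	position	ancestral	derived	frac_ancestral_hom	frac_het	frac_derived_hom
rs17112895	102057262	C	T	0.04	0.5	0.46
rs7909153	102056790	G	A	0.04	0.5	0.46
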