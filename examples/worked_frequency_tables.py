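"""Allele frequencies and two-locus LD from the bundled worked tables.

Loads the published Gumuz genotype fractions and worldwide two-locus
haplotype frequencies for the two TRPP3 substitutions (rs17112895 /
rs7909153) and prints the derived allele frequencies plus D' and r2 per
population.
"""

from sweepfunc.popstats import (
    allele_frequency_from_genotypes,
    ld_from_haplotype_freqs,
    load_genotype_fractions_table,
    load_haplotype_frequency_table,
)

print("Derived allele frequencies from Gumuz genotype fractions:")
for variant, g in load_genotype_fractions_table().items():
    print(f"  {variant}: {allele_frequency_from_genotypes(g):.2f}")

print("\nTwo-locus LD per population (derived-derived haplotype vs marginals):")
for pop, table in load_haplotype_frequency_table().items():
    try:
        ld = ld_from_haplotype_freqs(table)
        print(f"  {pop:8s} D'={ld.d_prime:.2f}  r2={ld.r_squared:.2f}")
    except ValueError as err:
        print(f"  {pop:8s} undefined ({err})")

print("\nD' = r2 = 1 means the two substitutions travel on the same haplotype;")
print("values are undefined where a locus is monomorphic (e.g. Europeans).")
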