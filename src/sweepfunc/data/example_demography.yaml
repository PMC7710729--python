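# Example three-population demography (African / European / Asian style
# topology) used for desk-scale neutral nulls and sweep power analyses.
# Sizes and times are scaled far below published demographic inferences so
# that thousands of replicate panels are cheap; the scaled per-bp diversity
# (4*N*mu = 4e-4) and the rec/mut ratio are kept in a plausible range, and
# the scanned population is census-sampled so window scores carry no extra
# binomial sampling noise.
epochs:
  - {population: AFR, size: 100, start_generation: 0}
  - {population: EUR, size: 15, start_generation: 0}
  - {population: ASN, size: 15, start_generation: 0}
splits:
  - {parent: AFR, child: EUR, generation: 40}
  - {parent: EUR, child: ASN, generation: 80}
migration:
  - {source: AFR, dest: EUR, rate: 0.002}
  - {source: EUR, dest: AFR, rate: 0.002}
  - {source: EUR, dest: ASN, rate: 0.002}
  - {source: ASN, dest: EUR, rate: 0.002}
mutation_rate: 1.0e-6
recombination_rate: 0.5e-6
sequence_length: 240000
generations: 120
samples:
  AFR: 100
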