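# Methods

`sweepfunc` chains four largely independent analyses — a haplotype-based
positive-selection scan with simulation-derived significance thresholds,
population-differentiation and linkage-disequilibrium statistics,
whole-cell patch-clamp quantification, and structural-ensemble
hydrogen-bond statistics — and ships a synthetic-data generator for each
stage so the whole chain is testable end to end without any external data.
This note records the models, the defaults and why they were chosen, and
what the synthetic data do and do not establish about real data.

## Wright–Fisher simulator

The generator is a discrete-generation forward simulator of diploid
Wright–Fisher populations with infinite-sites biallelic mutation (rate µ
per bp per generation, uniform integer positions), per-meiosis Poisson
recombination (mean r·L crossovers at uniform positions), random union of
gametes with selfing allowed, population splits (child founded by sampling
parent individuals with replacement), per-generation migration, and
optional selection at one site with genotype fitnesses 1 : 1+hs : 1+s. A
single forward code path serves both neutral nulls and sweeps, which keeps
the null and the alternative exactly comparable; the price is that burn-in
(default 8·N generations from a monomorphic state) dominates the cost of
one-off simulations. For replicate-hungry analyses two amortized entry
points (`simulate_replicate_panels`, `simulate_sweep_replicates`) burn in
once and sample panels from a single long run spaced by a configurable
number of generations (default 2·N). Spacing is a trade-off: successive
panels share ancestry that decays on the coalescent timescale, so residual
correlation at the default spacing slightly understates the
replicate-to-replicate variability of tail quantiles; the two-seed
agreement check on null thresholds uses fully independent runs precisely
so this shortcut cannot hide a bias.

Standing variation for sweeps has three origin modes because they probe
different science: `standing_instant` places the derived allele at
frequency f0 on random backgrounds (the analytic expectations — neutral
fixation probability = f0, deterministic trajectory, establishment
probability — condition on exactly f0); `single_mutation` lets one copy
drift, conditioned on survival, until it reaches f0 before selection
starts (the "previously neutrally segregating allele" scenario);
`standing_hard` plants all f0·2N copies on one donor haplotype, the
canonical hard-sweep signal a haplotype scan is calibrated against. The
power analysis uses `standing_hard`: in a desk-scale population the
conditioned drift phase of `single_mutation` lasts a sizeable fraction of
2N generations, which ages the sweeping haplotype so much that *no*
haplotype statistic could separate it from the null — an artefact of the
compressed timescale, not a property of the method.

Hot loops (crossover segment assembly, the pairwise-mismatch index and the
per-core EHH integration) have `numba` kernels with pure-NumPy/python
equivalents; the test suite asserts the two paths agree to 1e-9.

## Selection scan

For every biallelic core SNP with minor allele frequency strictly above
0.05, EHH is the probability that two random carriers of the same core
allele are identical over the interval from the core to an offset site,
computed separately for ancestral and derived carriers and in both
directions. iHH integrates each curve over physical distance (trapezoid
between informative sites), truncated at the last site with EHH ≥ 0.05
(the cutoff convention of the standard software; configurable). A core is
excluded — a typed outcome, never an exception — when either allele has
fewer than two carriers, when a gap larger than 20 kb between adjacent
sites is walked before truncation, or when an integral is zero. If the
panel edge arrives before the cutoff the record is kept and flagged
`truncated` (discarding edge cores, the usual genome-scan default, would
gut short synthetic panels). uiHS = ln(iHH_ancestral / iHH_derived), so
strongly *negative* scores mark unusually long derived haplotypes;
standardization to mean 0 / sd 1 within derived-allele-frequency bins of
width 0.05 removes the frequency dependence. In replicate runs the bin
statistics are pooled across all replicates (the analogue of genome-wide
standardization) and sweep panels are standardized against the pooled
neutral reference.

Windows tile the chromosome in non-overlapping 30 kb intervals anchored at
coordinate 0 (half-open, 0-based). Both window scores are always computed:
|mean(iHS)| (default, following the source convention of averaging scores
then taking the absolute value) and mean(|iHS|). The significance
threshold is the empirical 99.99th percentile (linear interpolation
between order statistics) of window scores under the neutral null; at
least 10^4 windows are recommended and a warning fires below that.

The sweep-power analysis uses the mean-|iHS| window score against that
score's own neutral percentile. The reason is structural: after an
incomplete hard sweep, hitchhikers riding the swept haplotype score
strongly negative while derived alleles displaced onto the shrinking
ancestral background score positive (their "ancestral" class now contains
the long swept haplotypes), and in a short simulated region the two groups
cancel in the signed mean. The magnitude score keeps both contributions.
Both scores are reported everywhere and the mode used is recorded in every
output row.

## Desk-scale study conditions

The bundled example demography is a three-population
(African/European/Asian-style) topology: ancestral population of N=100
diploids, two splits (generations 40 and 80 of a 120-generation epoch),
small sister populations (N=15) with symmetric migration 0.002, µ=1e-6 and
r=5e-7 per bp per generation over 240 kb, i.e. scaled diversity 4Nµ=4e-4
per bp and r/µ=0.5. The scanned population is *census-sampled* (all 100
individuals, 200 haplotypes): at this scale binomial sampling noise would
otherwise dominate the upper tail of neutral window scores. Null runs use
1250 panels per seed (10^4 window scores) spaced 300 generations apart.
Power uses sweeps at 2Ns=200 with dominant selection (h=1), f0=0.05 on a
single background, sampled when the selected allele reaches 80%
frequency, 50 replicates sharing one burn-in.

What passing these analyses shows: the estimator chain (EHH → iHH → iHS →
bins → windows → percentile threshold) is internally correct and has the
expected operating characteristics under a *scaled-down* Wright–Fisher
world whose per-window score distribution is self-consistently calibrated.
What it does not show: that any particular real genome scan's printed
critical value is recovered — that value depends on externally published
demographic parameters and replication far beyond desk scale — nor how the
scan behaves under real-data complications (genotyping error, phasing
switch errors, variable recombination maps, ascertainment).

## Population statistics

Allele frequency from genotype fractions is derived-homozygote +
heterozygote/2. Two-locus haplotype frequencies are plain counts over
phased haplotypes (missing alleles drop the haplotype from the
denominator). D is computed as the determinant dd·aa − da·ad (equal to
p11 − pA·pB but exact for the worked frequency tables), D′ = |D|/Dmax with
the usual frequency-dependent maximum, r² = D²/(pA(1−pA)pB(1−pB)); |D′| is
reported without sign. Per-site Fst defaults to the Hudson estimator with
sample-size correction — well-behaved under unequal sample sizes — and
negative corrected values are reported as computed; the uncorrected
plug-in form and two-population Weir–Cockerham are available and every
record names its estimator. Published frequency tables are rounded, so the
bundled-table loader renormalizes each row by its sum (one printed row
sums to 1.01).

## Patch-clamp quantification

Steady-state current is the mean over the final 10% of the 400 ms test
pulse (the averaging window is a package choice; no standard exists), and
the instantaneous tail is the extremum within 5 ms after repolarization
after a 0.5 ms capacitive blanking window; both are divided by membrane
capacitance (pA/pF) and both windows are configurable and logged. AUC is
the trapezoid over the voltage grid; steady-state AUC integrates positive
voltages only, tail AUC the full range (tail areas are typically
negative). Unitary amplitude is the mean spacing of adjacent component
means of a Gaussian mixture fitted to the sample-amplitude distribution
(k-means initialization, seeded); a fit whose component separation is
below 3× the narrowest component, or with a vanishing weight, raises
"components not resolvable". NPo = mean(|I − baseline|)/unitary amplitude
with the baseline taken from the largest-weight (closed) component —
justified because at hyperpolarized potentials open probability is low, so
the closed level dominates. The |·| estimator carries a small upward bias
of order (noise sd)/amplitude × P(closed); at the default synthetic
settings (sd 1 pA, amplitude 12 pA) this is ~5%, within the tolerance the
recovery checks use. Slope conductance is an ordinary least-squares fit of
unitary current on voltage over ≥3 negative potentials (pA/mV → nS, ×1000
pS); the intercept absorbs the reversal potential. Deactivation fits
I(t) = A·exp(−t/τ) + C by bounded least squares with data-driven initial
values. Recording duration is taken from the data and never hard-coded.

Synthetic gating traces advance N independent two-state channels at the
sampling interval with transition probabilities 1 − exp(−k·dt); the trace
is −(open count)·i_u + white Gaussian noise with i_u = g(V − E_rev), so
openings at negative potentials deflect upward as in a conventional
amplitude-histogram display. The discrete-time update is flagged (trace
metadata warning) when k·dt > 0.1. Real acquisitions are low-pass filtered
(1 kHz in the motivating setup); synthetic noise is white, so filter-induced
correlation effects on mixture fits are not exercised.

## Structural-ensemble statistics

Ensembles are directories of single-model PDB files. The contact distance
of a residue pair is the minimum Euclidean distance over the cross pairs
of named atoms (carboxylate OD1/OD2 are chemically equivalent; mean
reduction available). Classification is distance-only — bonded ≤ 3.5 Å,
marginal ≤ 4.0 Å (0.5 Å acceptance margin), non-bonded beyond — mirroring
a purely geometric criterion on static models; no donor–acceptor angle is
evaluated. Because "3.5 Å with a 0.5 Å margin" is ambiguous, both
thresholds appear in every report: the preserved-bond fraction counts
bonded ∪ marginal by default (configurable), while non-bonded statistics
are computed over the strict > 3.5 Å complement so the margin affects only
the fraction. Mann–Whitney U comparisons use the exact null distribution
when both samples have ≤ 10 observations without ties, otherwise the
normal approximation with tie and continuity corrections; the method used
is always reported.

The toy ensemble generator places the four analysis atoms (D390 OD1/OD2,
K452 NZ, K455 NZ) on a line per pair so that each pair's minimum distance
equals a sampled target (normal, or a Bernoulli bonded/non-bonded
mixture); only pairwise distances are meaningful, and PDB's three-decimal
coordinates bound the write/parse round trip at 10⁻³ Å. Non-bonded draws
in mixture mode are truncated above the acceptance threshold so the
planted bond probability is recovered exactly in expectation.

## Numerical and design notes

- All randomness flows from explicit integer seeds; library functions take
  a seed or a configured generator, and pipeline stages derive per-stage
  seeds from the run seed by hashing the stage name (crc32 xor), keeping
  every stage independently re-runnable below 2³¹.
- Percentiles use NumPy's linear interpolation between order statistics.
- Bin standardization uses the population (ddof=0) standard deviation so
  standardized scores have exactly unit sd within bins by construction;
  bins with fewer than two records or zero spread exclude their records
  rather than merging bins.
- Window tiles without scored SNPs are omitted; the minimum SNP count per
  window defaults to 1 and is recorded in output.
- VCF output writes the ancestral allele as REF with an `AA` INFO tag;
  reading polarizes against `AA` and skips sites whose tag matches neither
  allele (with a warning). Integration is over physical distance; a
  genetic-map hook exists in the design but the default map is uniform.

## Known limitations

- The forward simulator is infinite-sites biallelic with no gene
  conversion and no realistic chromosome-scale recombination map.
- Desk-scale populations compress the separation between sweep and
  coalescent timescales; power numbers quantify the scan under the bundled
  conditions, not on human-scale data.
- The Gaussian-mixture amplitude fit assumes well-separated open levels;
  heavily filtered or flickery single-channel data would need dedicated
  idealization, which is out of scope.
- Toy PDB models carry no chemistry beyond the four analysis atoms.
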