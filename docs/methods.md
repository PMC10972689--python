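# Methods

`bgsel` simulates background selection — the loss of neutral genetic
diversity caused by selection against deleterious mutations elsewhere in
the genome — in a multi-chromosome Wright–Fisher population, and
compares the simulated loss against closed-form predictions for linked,
unlinked, and combined effects.  This note records the model, the
measurement conventions, the numerical choices, and what the scaled-down
test conditions do and do not demonstrate.

## Model

**Population dynamics.**  N diploids reproduce in discrete generations.
Each offspring draws two parents independently, with replacement, with
probability proportional to fitness (selfing is possible; this is the
standard Wright–Fisher scheme).  Each parent contributes one recombined
gamete.  Census size is constant; simulations start mutation-free and
run 10N generations, which is several multiples of both the
mutation–selection-balance relaxation time (~1/sh generations) and the
neutral coalescent time (~4Ne), so endpoint measurements are taken at
equilibrium.

**Genome.**  23 chromosomes of equal length, measured in continuous
"genomic units" (100 units each by default).  Coordinates are real
numbers: under the infinite-sites assumption every new mutation occupies
a fresh position with probability one, so a position *is* a mutation's
identity.  Recombination is exactly two crossover points per chromosome
per transmitted gamete, i.i.d. uniform along the chromosome, with a
uniformly random starting strand per chromosome (free assortment between
chromosomes).  Two crossovers per chromosome puts the map length at
2 Morgans per chromosome, 46 M per genome.  An optional 24th chromosome
of the same length receives neutral mutations and crossovers but never
deleterious mutations, isolating purely unlinked background selection.

**Mutation.**  Deleterious mutations arrive at genome-wide rate U per
diploid per generation, implemented as Poisson(U/2) per gamete.  They
land uniformly over the 23 core chromosomes ("uniform" mode) or only
inside 1,000 genes covering 10% of the core genome ("genic" mode).
Since 1,000 genes do not divide evenly into 23 chromosomes, genes are
apportioned per chromosome as evenly as possible and then evenly spaced
and centred within each chromosome, so no gene straddles a chromosome
end and every chromosome is exactly 10% genic.  Neutral mutations
arrive at 1e-4 per unit per gamete — 0.23 per haploid genome on the
default architecture — uniformly over the whole genome including any
neutral chromosome.  The per-gamete reading of both rates is the one
that makes θ = 4Neμ hold in neutral calibration runs (inferred Ne ≈
census N at U = 0), which is the invariant that pins all rate
conventions.

**Selection.**  Fitness is multiplicative over sites with no epistasis:
heterozygous sites contribute (1 + sh), homozygous sites (1 + s) with
s = sh/h and dominance h = 0.5 throughout (additive).  The default
effect is a constant sh = −0.01, matching the mean of a human
non-synonymous DFE estimate (mean sNe = −224.33 at 2Ne = 23,646 gives
sh = h·s ≈ −0.0095); alternatively |sh| is drawn from a gamma
distribution with the same mean and shape α = 0.169.  Gamma draws are
capped at |sh| < 0.5 so the homozygote factor 1 + 2sh stays positive.
Fixed deleterious mutations multiply every individual's fitness by the
same constant, so they are purged from the bookkeeping (every 25
generations by default) without affecting relative fitness; fixed
neutral mutations are divergence, not diversity, and are likewise
removed but counted.

## Closed-form predictions

For a neutral site inside a genomic window with deleterious rate Uw and
map length Rw, linked background selection gives
Ne/N = exp(−Uw/(2sh + Rw)); for a large window this tends to
exp(−u/r), the ratio of deleterious mutation to recombination rates.
For freely recombining (unlinked) deleterious sites,
Ne/N = exp(−8·U·sh).  The joint model multiplies the two reductions,
excluding the focal window's mutations from the unlinked term to avoid
double counting:

    Ne/N = exp(−8·(U − Uw)·sh) · exp(−u/r)

with 20,000 windows by default.  Because the default joint variant uses
u/r = (U/n)/(L/n) = U/L, it is exactly window-count-free; the variant
built from the finite-window formula varies by <1% over 10,000–40,000
windows.  Note the two regimes pull opposite ways with selection
strength: stronger selection *weakens* linked background selection
(deleterious alleles die before recombination matters) but
*strengthens* unlinked background selection.  u/r is evaluated
genome-wide as U divided by the total map length, treating the genome
as homogeneous.

## Measuring diversity and Ne

Neutral mutations are carried forward explicitly in the simulation and
diversity is computed from final-generation allele frequencies (the
expectation at stationarity is the same as overlaying neutral mutations
on recorded genealogies, and the neutral-calibration invariant checks
the implementation end to end).  One endpoint measurement per run;
replicate simulations, not time averages, supply error bars.

*Infinite alleles* (whole genome): the genome is partitioned into loci
of 0.1 units; a haplotype's allele at a locus is the exact set of
neutral mutations it carries there, haplotypes with none sharing the
ancestral allele.  Per-locus expected heterozygosity uses the unbiased
estimator (2N/(2N−1))(1 − Σp²), averaged over all loci including
variation-free ones, and Ne is inverted from H = θ/(1+θ) with θ = 4Neμ
per locus.  The locus length matters: the θ/(1+θ) identity probability
assumes a single coalescent tree per locus.  In a recombining genome a
long locus mixes genealogies, pushing heterozygosity toward 1 − e^(−θ)
and inflating the inverted Ne by roughly θ/2 — an N-dependent artifact
(~+9% at N = 500, ~+17% at N = 1,000 for 1-unit loci) that would
masquerade as census-size dependence of background selection.  At 0.1
units, θ per locus stays below ~0.04 for the census sizes used here and
the residual bias is ~1–2%.

*Infinite sites* (genic / intergenic / neutral-chromosome): per-site
pairwise diversity 2p(1−p), with the same unbiased correction, summed
over segregating neutral sites in the region and divided by region
length, inverted through θ = 4Neμ.  This sidesteps allele bookkeeping
inside short gene intervals (each gene is only 0.23 units).

## Index of dispersion

The genome-wide signature of nonindependent evolution is the index of
dispersion of deleterious load: the sample variance (denominator 2N−1)
of the number of deleterious alleles per haplotype — a haplotype being
all chromosomes from one parent — divided by its mean.  Independent
sites give 1 (Poisson); negative inter-locus correlations created by
selection against unlinked combinations push it below 1.  It is
undefined (an error, not 0/0) when no deleterious alleles segregate.
Replicate sweeps report mean ± SE over (by default 11) independently
seeded runs, measured at each run's final generation.

Neutral mutations cannot influence the deleterious load: fitness reads
only deleterious sites, and the parent, recombination and mutation
random streams are independent, so deleterious transmission is
unchanged by neutral bookkeeping.  Load-only experiments (the
dispersion sweeps) therefore run with the neutral rate set to zero; the
load distribution is statistically identical and the runs are ~40%
faster.

## Numerical design

* **State layout.**  Each haplotype's mutations live in two ragged
  CSR-style arrays (deleterious and neutral stores), sorted by
  position.  Fitness walks only the deleterious store; diversity only
  the neutral one.  Compiled (numba) kernels do the per-generation
  work: a merge-walk over each diploid's two haplotypes for fitness,
  and segment-wise transmission that exploits the fixed two-crossover
  structure (each transmitted chromosome is three contiguous segments,
  copied from the active strand with new mutations merged in order).
* **Randomness.**  One master seed spawns three named generator streams
  (parent sampling, recombination, mutation), so runs are bit-for-bit
  reproducible and the streams stay aligned under changes to any one
  consumer.  Sweep cell r of cell i uses seed base + i·replicates + r.
* **Effects in float32.**  Positions (identities) are float64;
  selection coefficients are stored in float32 and origin generations
  in int32 to halve memory traffic.  With the constant DFE the
  generation step uses an exact count-based fitness kernel (n_het,
  n_hom), which it falls back from automatically if a population
  carries mixed effects.
* **Degenerate cases.**  sh = 0 with Rw = 0 in the window formula is
  defined as ratio 1 only when Uw = 0, otherwise rejected.  Crossover
  ties and mutation-position collisions are measure-zero and unhandled.
  A population whose fitnesses are all non-finite raises rather than
  silently renormalising.
* **State files** are plain TSV haplotype–mutation tables written with
  `%.17g` floats and re-read with correctly-rounded parsing, because a
  position that changes by one ulp would become a different mutation.

## Scaled test conditions

Full-scale versions of these experiments (N = 5,000–10,000 for 10N
generations) are cluster-sized jobs; desk and CI runs here use N = 500 (N = 50 for neutral calibration,
N = 250–1,000 for specific checks), keeping every rate, the genome, and
the 10N duration unchanged.  Consequences to keep in mind:

* Scaled-down census sizes reduce 2N·sh (10 at N = 500 with the default
  sh versus 100–200 at full scale), so weak-selection deviations from
  the deterministic formulas are larger here: the simulated whole-genome
  Ne/N sits above the joint prediction (about 0.88 versus 0.82 at U = 2,
  sh = −0.01; still inside a ±0.1 band).  Across both sh = −0.01 and
  sh = −0.05 the measured unlinked log-reduction is roughly half of
  8·U·sh — compatible with a factor-two haploid/diploid ambiguity in
  the unlinked formula's rate convention as much as with weak
  selection; this package defines U strictly per diploid offspring.
* Two qualitative signatures are regime-limited at desk scale.  With
  2N·sh ≈ 5 the genic-versus-intergenic diversity gap can invert
  (associative overdominance: weakly selected linked variants *shelter*
  diversity), so the genic ≤ intergenic ordering is not asserted at
  sh = −0.01, N = 250; the desk-robust Fig-2-style properties are that
  concentrating deleterious mutations into genes weakens overall
  background selection and that the deleterious-free chromosome loses
  about as much diversity as intergenic sequence.  Likewise, at
  2N·sh ≈ 10 weakly selected sites drift to appreciable frequencies
  and push the dispersion index below 1 even at U = 0.1 (a
  binomial-sampling effect, not inter-locus correlation), so the
  low-U "index ≈ 1" independence regime is exercised at sh = −0.05,
  where 2N·sh ≈ 50 matches the effective-selection regime of the
  full-scale conditions.  The headline underdispersion condition
  (U = 4, sh = −0.01) is kept exactly as stated.
* Sweeps default to a single replicate per grid cell (spending compute
  on a denser parameter grid rather than on replicates); replicate error bars are used only
  where a mean is asserted (dispersion, calibration).
* The synthetic data generator *is* the study system: no empirical
  genomes are modelled, and nothing here speaks to features the model
  omits — variable recombination, non-additive dominance, beneficial
  mutations, demography, or real human gene structure.

## Known limitations

* The transmission kernel hard-codes at most two crossovers per
  chromosome (the study's regime); more would need the full crossover
  list rather than the two extreme points.
* Mutation registry ids are snapshot ordinals; durable identity across
  generations is the (unique) position.
* The infinite-alleles locus construction is a reconstruction validated
  by calibration, not a published convention; its granularity trades
  resolution against the single-tree bias discussed above.
* Between purges (25 generations), a mutation that fixes is still
  carried by all haplotypes; statistics that read carrier counts should
  run after `purge_fixed()`, as `run_simulation` does before returning.
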