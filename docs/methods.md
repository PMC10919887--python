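# Methods

## The model

`zwturnover` simulates the microevolution of a master sex-determining gene
on an undifferentiated ZW chromosome pair, of the kind found in several
carangid fishes where sex is decided by a single variant in a gene
required for female development.  The model has three ingredients:

1. **Sex is an emergent property of genotype.**  A chromosome whose copy
   of the focal gene is fully functional behaves as W; a copy carrying
   any loss-of-function (LOF) change behaves as Z.  An individual with at
   least one functional copy develops as a female, one with two
   nonfunctional copies as a male.  There is no other fitness component:
   purifying selection on W and near-neutral evolution of Z both emerge
   from this rule alone, because a population must contain both sexes to
   reproduce.
2. **Mutation on a finite-sites gene segment.**  The gene is a 1,678-bp
   segment with explicit exon/intron structure.  Point mutations arrive
   at rate mu per site per generation at uniform positions, each to a
   uniform choice among the three alternative bases of the *current*
   base, so recurrent and back mutation are possible.  A change is LOF
   when it is missense, nonsense, or hits a splice donor/acceptor
   dinucleotide (GT/AG); synonymous and intronic changes are neutral.
   Effects are classified against the reference codon, making the effect
   a pure function of (position, base) that is precomputed once per gene
   model.  A premature stop is treated as LOF on the reasoning that it is
   at least as disruptive as a missense change; loss of the terminal stop
   codon is likewise classed with missense.
3. **Divergence-dependent recombination.**  At meiosis a single crossover
   occurs with probability `min(1, L * r)` where
   `r = r0 * max(0, 1 - c * d)`, `d` is the raw count of sites at which
   the parent's two haplotypes differ, and the breakpoint is uniform on
   internal boundaries.  With the default coefficient `c = 0.03`,
   recombination stops entirely once homologs differ at 34 or more
   sites.  `d` is a count rather than a proportion: as a proportion the
   suppression term would be negligible at these rates and the clamp
   unreachable.  Multiple crossovers per meiosis are not modeled; at the
   rates considered here the probability of two crossovers in one meiosis
   is below (1.7e-3)^2 and their effect is invisible against the
   single-crossover dynamics.

Reproduction is Wright-Fisher with nonoverlapping generations and
constant size N = pop_chromosomes/2: each offspring draws a mother
uniformly from the females and a father uniformly from the males, with
replacement.  The founding state is ceil(N/2) W/Z females and the rest
Z/Z males, where every Z carries exactly one LOF change at the first
intron's splice-donor G (a G>A change), mirroring the natural situation
in which the study species' Z-linked allele disrupts the donor site.  If
a generation is produced with zero females or zero males before the
scheduled end, the replicate terminates with a recorded
`extinct_single_sex` status; at 2N = 100 this has probability ~2^-49 per
generation and never occurs in practice.

## Census and turnover

At the end of a replicate every haplotype is classified W-class
(functional) or Z-class (nonfunctional).  LOF positions carried by all
Z-class haplotypes are *fixed*; those carried by some but not all are
*nonfixed* (fixation is assessed among Z-class chromosomes, the only
place a LOF change can reside).  Two derived bases at one position count
as one sex-determining position.  A *turnover* requires the final state
to carry exactly one fixed LOF position, different from the founding
site, with no nonfixed LOF positions remaining — i.e. the founding
mutation has been completely replaced by a new one.  Batches aggregate
into a table of turnover percentage (TS) and histograms of replicates by
fixed and nonfixed LOF counts.

## Diversity statistics

pi (within the whole population, the W class, and the Z class) is the
mean pairwise difference count per segment over unordered pairs of
chromosomes; d_xy is the mean over W x Z cross pairs; Fst is
`1 - mean(pi_w, pi_z) / d_xy` (undefined, reported as NaN, when
d_xy = 0).  Counts are reported per segment, matching the convention of
"average number of nucleotide differences between segments"; per-site
scaling is an explicit option.  The implementations operate on collapsed
(haplotype, count) inventories and are tested for exact equality against
brute-force double loops over fully reconstructed sequences.

## The two engines

The naive engine materializes every individual and every meiosis; it is
transparent and is the reference for distributional checks.  The default
*counts* engine represents the population as genotype counts (unordered
pairs of interned haplotype ids).  Because offspring are iid given the
current state, one generation is: build the maternal and paternal gamete
distributions as mixtures over parent genotypes, draw N gametes per side
count-wise (crossover and mutation products are materialized
individually — they are rare at the study's rates), and pair the two
pools uniformly at random via sequential multivariate hypergeometric
draws.  Cost per generation is O(k^2) in the number k of distinct
haplotypes, independent of N.

When exactly two haplotypes segregate — one W, one Z, with genotypes
{W/Z females, Z/Z males} — consecutive generations are iid: every
offspring is female with probability 1/2 and the gamete distribution does
not depend on the current female count.  The engine then jumps directly
to the next generation containing an event (a mutation anywhere; or a
maternal crossover when d(W,Z) >= 2, since for d = 1 a crossover cannot
produce a new haplotype), drawing the jump length from the exact
geometric law, the female count at the event generation from a
Binomial(N, 1/2) conditioned on both sexes being present, the event
counts from their distributions conditioned on at least one event, and
accounting for single-sex extinction inside the skipped block with the
exact geometric tail.  This is an exact acceleration, not an
approximation; the test suite compares the two engines over 200
replicates at 2N = 20 and 500 generations (elevated rates so that events
are common) with two-sample tests at alpha = 0.01 on the final sex
ratio, pi, and segregating-site counts.  A 100,000-generation replicate
at 2N = 100 takes a fraction of a second; at 2N = 10,000 about 15 s.

## The synthetic gene segment

The study's actual 1,678-bp segment is not published, so the default
gene model is generated: two exons covering half the segment (the
coding fraction is configurable; the turnover tallies depend on it
through the LOF target size), assembled codon-by-codon from sense codons
with a terminal stop so the spliced frame is clean, introns opened with
GT and closed with AG, and the founding G>A mutation at the first
intron's donor.  Under the standard genetic code about three quarters of
exonic changes are amino-acid-changing, so with a 0.5 exon fraction
roughly 38% of all possible changes are LOF.  The generated segment is
deterministic given its seed; seed 7 is the fixed default used by the
bundled configuration and the acceptance script, playing the role of
the one fixed natural gene segment.  What the generator does *not*
emulate: real codon usage, splice-strength variation, the 64-nt
alternative-donor extension observed in the real transcript (binary
functional/LOF suffices for the simulation), or any regulatory sequence.
Conclusions transfer to real data only insofar as the LOF target size is
realistic.

## Cohorts and coverage tracks

The association statistics are exercised on synthetic cohorts: one
causal variant with a perfect female-heterogametic pattern (every female
heterozygous, every male homozygous for the derived allele — either a
SNP or a 4-bp indel, as presets mirroring the 45F/37M and 14F/7M cohort
shapes), plus background SNPs drawn independently of sex in
Hardy-Weinberg proportions with allele frequencies uniform on
[0.05, 0.5].  Because background genotypes are exchangeable between the
sexes, null association p-values are uniform, which the suite checks
with a Kolmogorov-Smirnov test over 1,000 sites.  The genotypic test is
a Pearson chi-square without continuity correction, by default on the
heterozygous-vs-homozygous 2x2 collapse (1 df) — the unique standard
test that reproduces the printed p = 1.36e-19 from the printed counts;
a full 2x3 (2 df) variant is available.  For the 14F/7M indel table the
closed form gives chi-square = 21, p = 4.58e-6, against a printed
4.5e-6; the package reports the computed value and treats the printed
one as truncated.  Coverage tracks are two iid gamma tracks with a
common mean, so the expected log2((male+0.1)/(female+0.1)) ratio is zero
per window, the expectation for a fully undifferentiated chromosome.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; 1-based only at the VCF
  boundary.
* Seeds: one base seed per batch, replicate i uses `base_seed + i`;
  identical (params, seed, engine) give bit-identical results.
* Diversity on groups of fewer than two chromosomes, and Fst with
  d_xy = 0, are NaN, never exceptions.
* The aggregation bins replicates by LOF count as 0,1,2,3,4+ (fixed) and
  0..4,5+ (nonfixed).
* The recombination coefficient is exposed so both readings of the
  divergence term (fraction removed per difference vs a multiplicative
  factor) can be explored; the default subtractive reading recovers r0
  at d = 0 and yields progressive suppression.

## Problem sizes used by the checks

The bundled acceptance checks run what a single CPU handles in minutes:
the two 2N = 100 parameter sets at full scale (100 replicates x 100,000
generations, ~1 min each), a 2N = 1,000 vs 2N = 100 comparison (50
replicates each) for the large-population behavior, and a six-replicate
probe at the full 2N = 10,000.  A complete 100-replicate batch at
2N = 10,000 takes roughly half an hour per set with the counts engine
and is left to the user (`zwturnover simulate --builtin table1 --set
Set3 --set Set4`).

## Known limitations

* No selection coefficients, demography, overlapping generations, or
  male-heterogametic (XY) mode.
* Single crossover per meiosis; no gene conversion.
* Classification ignores other segregating changes in the same codon
  (single-site effects only).
* The desk-scale 2N = 1,000 comparison of co-segregating nonfixed
  mutations is statistically underpowered at 50 replicates: the
  proportion carrying >=2 nonfixed LOF mutations at the final state is
  only a few percent at 2N = 1,000 (vs roughly two thirds at
  2N = 10,000), so the prescribed alpha = 0.01 two-proportion test
  rarely rejects.  The corresponding check is expected to fail at that
  scale; the full-scale probe in the same test demonstrates the
  qualitative behavior directly.
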