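# Methods

`allobreed` is a stochastic simulator for breeding programs of
allogamous (obligately outcrossing) crops, built around a tall-fescue
style commercial program and the question of what genomic selection
(GS) combined with speed breeding (SB) does to genetic gain, prediction
accuracy and inbreeding.  This note records the models, the parameter
choices, the numerical decisions, and what the reduced-scale test suite
does and does not demonstrate.

## 1. Base-population model

The crop is an allohexaploid (2n = 6x = 42) whose three subgenomes pair
strictly within themselves, so every chromosome behaves as an
independent diploid chromosome and the simulator treats the hexaploid
as a diploid with 21 chromosomes (full scale: 3 ancestors x 7
chromosomes x 10^5 equally spaced biallelic loci on 100 cM maps).

Demographic history: a common diploid ancestor starts monomorphic and
accumulates mutation-drift variation; three speciation events
(generations 8,000 / 8,200 / 15,000 at full scale) found the three
diploid progenitors through a 10% founding bottleneck with geometric
expansion back to census size over 100 generations.  The first two
diploids hybridize into the tetraploid (generation 16,000), which
hybridizes with the third into the hexaploid (generation 25,000).
Hybrid offspring receive a full homologous pair per parental
chromosome, built from two independent gametes of one parent
individual — chromosome sets concatenate (7+7 = 14, 14+7 = 21).

Per generation: random mating between two distinct parents (no
selfing — the species is self-incompatible), Poisson(lambda = 1)
crossovers per chromosome at uniform map positions with no
interference, and per-allele-copy mutation at rate mu = 10^-5 realised
as an allele flip (the two-allele analogue of infinite sites, which is
what the equilibrium formula E(He) = 4 Ne mu / (8 Ne mu + 1) assumes).
The printed stop generation of the source design is internally
inconsistent with the event schedule, so the run end is governed by an
equilibrium diagnostic: every 5,000 generations (scaled presets: every
80) the hexaploid's mean heterozygosity is compared with the
closed-form expectation; the run stops once it is within two standard
errors (estimated from per-chromosome means, conservative under
linkage) at two consecutive checkpoints, or at a hard
`end_generation`.

Cultivars: 20 populations, each founded by 1,000 random base plants and
closed-random-mated for 100 generations with no mutation.  No mutation
occurs anywhere downstream of the base population (stated for
cultivars; extended to the breeding program for consistency).

## 2. Trait architecture

Five traits with narrow-sense heritabilities: heading date HD 0.7,
forage yield FY 0.3, seed yield SY 0.4, quality Q 0.3, persistency Per
0.1.  Each trait has 1,000 additive QTL drawn from loci with base MAF
> 5%.  FY, SY and HD share a 500-locus pleiotropic block; Q and Per
are disjoint from everything.  FY-SY and FY-HD genetic correlations
target 0.2 and 0.3.

Effects: FY, SY, Per ~ N(0, 1).  HD and Q mix l large-effect QTL
(HD: 20, Q: 100) drawn from N(0, m) into a unit-variance polygenic
background, with m = e (n - l) / (l (1 - e)) so the large class
explains e = 50% of the effect variance.  (The printed form of this
formula in the source is typographically corrupted; the implemented
form is the unique solution of l m / (l m + n - l) = e.)  "N(0, m)" is
read as variance m, consistent with N(0, 1) denoting unit variance.

Correlated mixtures: because mixture columns do not have identity
covariance, the standard `chol(C)` recipe does not apply.
`correlate_effects` whitens the raw matrix R with the inverse Cholesky
factor of its own second-moment covariance (about zero — effects are
zero-mean by construction) and colours it with the Cholesky factor of
the target C, giving exactly-C sample covariance even for mixtures.
Columns are then rescaled to their input root-mean-square so each
trait's marginal effect-variance structure survives.  Ordering the
mixture trait first makes the triangular transform leave its column
untouched (up to scale), so HD's large/small structure is preserved
exactly; this orientation is pinned by unit tests.

Where C applies: the source is silent on whether the target
correlation is imposed genome-wide or block-wise.  Here it is imposed
on the shared block only, with the within-block correlation inflated
by 1/sqrt(w_s w_t), where w_t is the shared block's (theoretical)
share of trait t's effect variance, so the genome-wide genetic
correlation hits the target.  HD's 20 large QTL are placed inside the
shared block (w_HD = 0.745 at full scale), which is also the case the
new method exists for.  Validation is empirical: realized TBV
correlations in the base population recover the targets within +-0.05
over repeated QTL draws.

TBV and phenotype: TBV = sum of effects x allelic dosage (0/1/2);
phenotype = TBV + N(0, sigma_e^2), errors independent across traits,
with sigma_e^2 = Var(TBV) (1 - h2) / h2 recomputed from each cycle's
initial cohort so realized h2 stays nominal as genetic variance
erodes.  Plot-level phenotypes use the plot-mean TBV plus an error
whose variance is set from the between-plot TBV variance so plot-level
h2 equals the trait h2 (the source gives only single-plant h2).

## 3. Breeding schemes

Phenotypic program (PS, 11 years/cycle at full scale):

1. *Crossing* (1 y): 20 cultivars -> 10 uniformly random disjoint
   pairs; 5 plant-to-plant crosses per pair x 100 seeds = 50 full-sib
   F1 families, 5,000 plants.
2. *Topcross* (2 y): cull the earliest-heading 20% (lowest HD
   phenotype — larger phenotype = later heading), keep the SY top 60%
   of the original count among survivors, draw 100 plants uniformly
   from that pool.
3. *Small plots* (2 y): one 500-seed plot per selected mother,
   open-pollinated by random HD-surviving topcross plants; top 40
   plots by the equal-weight standardized FY + Per plot index; within
   each, 25 random clones from the top 80% by individual FY + Per.
4. *Single rows* (3 y): 1,000 rows; top 500 by Q phenotype.
5. *Synthetics* (1 y): rows sorted by HD and partitioned consecutively
   into 50 synthetics of 10, so each synthetic's parents flower
   together.
6. *Field trial* (2 y): large plots of random-mated synthetic seed;
   top 20 by the FY + Per plot index become next-cycle cultivars (a
   cultivar = the pooled plants of its synthetic's plots).

SpeedGS scenarios replace stages 1-2 with a one-year stage of 1-3
(up to 6) SB rounds and omit stages: S1 keeps everything (9 y), S2
drops single rows (6 y), S3 drops small plots (7 y), S4 drops both
(4 y).  Each SB round genotypes the 1,000-plant pool, predicts
five-trait GEBVs, standardizes them within the cohort, forms the index
0.35 Per + 0.25 FY + 0.15 SY + 0.15 Q + 0.10 HD, ranks all
1,000*999/2 = 499,500 parent-pair index averages, and draws 1,000x1 or
100x10 crosses uniformly from the top 10,000 pairs.  SNP effects are
estimated once per cycle and reused across rounds.

Gaps the source leaves open, resolved as follows: small-plot mothers
in S1/S2 are the top-index GEBV plants of the SB output (the output
pool also donates the pollen); where a scenario omits the stage that
would have produced HD/Q/SY phenotypes, selection and HD grouping use
GEBVs (single-row selection in SpeedGS scenarios adds SY to the Q
index, per the stated design); "field trial size 100 instead of 50"
in S3/S4 is implemented as 2 replicate plots per each of the 50
synthetics, with synthetics ranked by the mean of their plots' index —
this keeps the synthetics stage intact and the 10-vs-5 synthetic-size
variant meaningful.  All ties anywhere break by a seeded uniform draw.

Program accounting: 4 PS warm-up cycles, then 4 SpeedGS cycles plus a
final initial population generated only to track gain.  The first GS
pool is 1,000 plants drawn from the unselected 5,000 of the
cycle-5 crossing; later cycles build theirs from the new cultivars via
the configured (crosses x progeny-per-cross) design, default 50x20 —
the source's "50 crosses x 100 plants" conflicts with the stated
1,000-plant pool, so the cross count is kept and the product forced to
1,000.  Inbreeding-mitigation variants: synthetics of 5 instead of 10,
and initial designs 100x10 / 200x5 / 1000x1.

## 4. Genomic prediction

Panel: 100,000 SNPs drawn from loci with base MAF > 5% after excluding
every trait's QTL (masking the causal variants).  The counted allele
is the base minor allele and the coding is persisted so retrained
models stay comparable as loci drift, possibly to fixation.

Reference: pooled plot genotypes — per SNP, 2 x the counted-allele
frequency among 20 randomly sampled plants (a value in [0, 2]) — with
plot-level phenotypes.  Every plot entering the reference is
phenotyped for all five traits at plot level; without this the three
traits not measured at the plot stages would have no training data at
all, contradicting the requirement that the prediction equation be
trained for all five traits.  The reference starts with the 400 small
plots of the warm-up cycles and grows by 150 plots per cycle (S1, S2:
100 small + 50 large) or 100 (S3, S4: large only).

Model: Bayesian ridge regression per trait — Gaussian coefficient
prior with one common variance, scaled-inverse-chi-square hyperpriors
(df 5, scales matched to a prior variance split at the trait's h2) on
both variances, estimated by a Gibbs sampler (full scale: 50,000
iterations, 10,000 burn-in) that accumulates the full-conditional
means (Rao-Blackwellization) to cut Monte-Carlo error.  With the
variance ratio fixed, the posterior mean equals the ridge solution
(Zc'Zc + lambda I)^-1 Zc'yc (dual form when markers outnumber rows);
this closed form is the default for reduced-scale runs and the oracle
the sampler is tested against (agreement to <= 1% on small instances).
Candidates carry integer dosages, reference rows fractional pooled
dosages; both feed the same model.  GEBV = Z beta-hat; accuracy =
Pearson correlation of GEBV with TBV, recorded per trait, SB round and
cycle on the current round's candidates.

## 5. Metrics

Standardized gain Delta-sigma_g = (mean TBV_ci - mean TBV_c5) /
sd TBV_c5, baselined at the first GS cycle's initial population.
Inbreeding via the VanRaden method-1 GRM with allele frequencies
frozen at that same baseline: F = mean diagonal - 1;
Delta-F = (F_c - F_{c-1}) / (1 - F_{c-1}) (the chain of per-cycle
rates reconstructs 1 - F exactly).  SNPs monomorphic at baseline
contribute zero and are retained.  Panel heterozygosity is tracked per
cycle.  Scenario contrasts use the pooled-variance two-sample t-test
(Welch by flag) at p < 0.01 with no multiplicity correction, matching
the study convention.

## 6. Scale presets

The full-scale run (10^4 individuals x 2.1M loci x ~10^5 generations,
100k-SNP BRR at 50k iterations, 100 replicates) is cluster-scale.  The
`desk` preset keeps every code path and the quantities that control
the dynamics, and shrinks everything else:

* base population: N = 100, mu = 10^-3 (4 N mu = 0.4 preserved, so the
  equilibrium E(He) = 0.222 is unchanged), 3 single-chromosome diploid
  ancestors x 2,500 loci, events at generations 150/160/300/330/520,
  hard end 1,000 (the equilibrium stop typically fires near 800);
* cultivars: 80 founders, 8 closed generations (drift fraction
  generations/2N = 5%, as at full scale);
* traits: 500 QTL per trait, 250 shared, HD l = 10 / Q l = 50 (the
  variance multipliers m = 49 and 9 are scale-free);
* scheme: topcross 1,000; 50 small plots of 60; 500 rows -> 250
  selected (the full-scale 50% fraction); 25 synthetics of **10** —
  the synthetic parent count is kept at full scale because
  within-synthetic drift 1/(2 x size) dominates the per-cycle
  inbreeding increment and halving it distorts Delta-F badly; GS pool
  500 with pair cap 2,500 (~2% of pairs, as 10,000/499,500) and
  crossing defaults 500x1 / 50x10; initial design 20x25; 2 warm-up +
  2 GS cycles; 800-SNP panel; ridge instead of Gibbs.

A `micro` preset (N = 60, 400 loci, pool 60) exists for smoke tests
and CLI runs.  Replicates at desk scale share one base population and
redraw cultivars, QTL, effects and all breeding randomness; scenario
cells within a replicate branch from the same warm-up snapshot, giving
paired comparisons.  Seeds derive from a master seed via a
SeedSequence hierarchy (base -> replicate -> cell), so runs are
bit-reproducible from the manifest and independent of execution order.

## 7. What the reduced-scale suite shows — and what it cannot

At desk scale with 20 paired replicates the suite reproduces the
study's qualitative structure: realized h2 constant per cycle (within
0.03), genetic correlations and the HD large-QTL variance share
recovered, baseline GRM diagonal ~1; per-cycle gain non-decreasing in
SB rounds, GEBV accuracy declining across rounds with a larger
round-1->2 than round-2->3 drop, Delta-F increasing with SB rounds
(desk S4/3-round Delta-F ~0.22, close to the full-scale report),
all-distinct-cross initial populations reducing Delta-F, and the SB
crossing scheme (500x1 vs 50x10) moving Delta-F but not mean gain
beyond noise.

Not resolvable at this scale: the late-round accuracy *plateau* in a
six-round run (it needs the dense panel and persistent LD of the
full-scale genome; at desk the decline continues through round 6, and
the test asserts only the overall decline), full-scale Delta-F
magnitudes for the mitigation variants, and anything that depends on
2.1M-locus LD structure.  The synthetic base population also omits
real-genome features — uneven marker density, structural variation,
homoeologous exchange, multi-allelic loci, dominance/epistasis and
genotype-by-environment interaction are all out of scope — so passing
tests certify the algorithms and the stated model, not field
performance.

## 8. Numerical notes

* Meiosis is vectorized: per-interval Poisson crossover counts (their
  sum per chromosome is exactly Poisson(lambda)), parity cumsum for
  the haplotype phase, `take_along_axis` for the gamete.
* Mutation draws a binomial count of allele copies and flips them by
  index (double hits cancel, matching independent flips).
* Degenerate inputs: constant phenotype vectors give intercept-only
  models with a warning; zero-variance GEBV/TBV vectors record NaN
  accuracy; empty LD summaries are flagged rather than raised;
  whitening refuses numerically rank-deficient effect matrices.
* Standardization is always within the cohort being selected, with
  zero-SD columns mapping to zeros (pure tie-break selection).
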