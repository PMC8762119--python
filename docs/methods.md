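# Methods

## Demographic model and coalescent simulator

Haplotype panels are generated under the structured coalescent with
recombination.  The default demography (`pig_demography_model()`) describes four
related pig populations: backward in time, P4 merges into P3 at 20
generations, P3 into P2 at 200, P2 into P1 at 3,000, and P1 into an
ancestral population P0 at 9,000 generations; the ancestral population's
origin is recorded at 58,000 generations.  Diploid effective sizes are
N0 = 10,873, N1 = 1,600, N2 = 1,200, N3 = 1,000, N4 = 1,400; symmetric
per-generation migration connects (P0,P1) at 2.1e-5, (P1,P2) at 1.1e-3,
(P1,P4) at 3.7e-4, (P2,P3) at 5.2e-5 and (P3,P4) at 1.6e-3, each pair
active only while both demes exist.  Mutation and recombination rates are
both 1e-7 per bp per generation on a 10 Mb chromosome.

Two aspects of this demography are interpretations rather than ground
truth, and are configurable:

* **Split topology.**  The published event times and rates do not pin down
  the divergence tree.  The serial chain above (P4→P3→P2→P1→P0) is one
  consistent reading; the observed kinship structure (P1-P4 less related
  than P1-P3) could also support P4 branching directly off P1 with the
  (P1,P4) migration supplying the residual affinity.  The topology is a
  plain list of split events in `DemographicModel.events`.  A visible
  consequence of the default chain: P3 and P4 are near-equidistant from P1
  (P4 adds only 20 generations of extra divergence while its direct
  migration link to P1 pulls it back), so accuracy contrasts between P3 and
  P4 references are within noise at desk scale; trend assertions therefore
  compare the near populations (P1, P2) against the far ones (P3, P4)
  rather than ordering the far pair.
* **Role of P0 and the origin time.**  P0 is modelled as an unsampled ghost
  deme extant to the present, which makes the (P0,P1) migration rate
  meaningful throughout; the origin time is metadata with no structural
  effect.  Bottlenecks beyond the constant per-deme sizes are not added.

The simulator is a Hudson-style backward algorithm on the ancestral
recombination graph.  Each lineage carries a sorted set of half-open
ancestral segments `[a, b)` annotated with the genealogy node and the
number of sampled haplotypes beneath.  Waiting times are exponential in the
total intensity; coalescence in a deme with `k` lineages and size `N`
occurs at `k(k-1)/2 / (2N)` per generation (continuous time, diploid Ne),
migration moves single lineages at `k_x * m_xy`, and recombination splits a
lineage at a uniform continuous breakpoint within its ancestral extent at
rate `r * span`.  Coalescence records node/edge table entries (tskit-like
layout); segments that reach the sample-wide MRCA are retired, and the run
ends when every locus has fully coalesced.  Split events move all lineages
of the derived deme into the ancestral deme.  A union-find connectivity
check over splits and positive migration pairs rejects models whose sampled
demes can never share an ancestor, before any simulation.

Mutations follow the infinite-sites model: each edge receives a Poisson
number of mutations with intensity `mu * branch_length * edge_span`,
positions are uniform within the edge interval and floored to unique
integer bp (collisions redrawn within the interval); carriers are the
sampled haplotypes below the mutated edge in the marginal tree at that
position.  Only segregating sites are emitted, which holds by construction
because edges above a local MRCA are never created.  Internal coordinates
are 0-based half-open; VCF export is 1-based.

One run seed drives everything; ancestry and mutation sub-streams are
derived deterministically from it (`numpy.random.SeedSequence.spawn`), so
each stage is independently reproducible and identical seeds give
bit-identical panels.  An optional adapter delegates ancestry simulation to
msprime behind the same `GenealogyForest` interface; the test suite also
uses msprime as an independent distributional cross-check (mean TMRCA under
split and migration models) but never requires the adapter for the
pipeline itself.

## Marker ascertainment

The imputable variant universe keeps biallelic sites with minor-allele
frequency >= 0.01 (inclusive) computed on the target cohort only — by
default the first individuals of P1, matching how the benchmark defines its
target population.  Scaffold markers are then drawn at a density level
`p` in {1, 5, 10, 30, 50, 90} %, with the marker count `floor(p * S)`
(floor verified cell-by-cell against the published count table):

* **chip** — deterministic, evenly spaced in *site rank*: rank `j` maps to
  index `round_half_up(j (S-1)/(count-1))`.  Rank spacing is density-exact
  and deterministic; spacing in bp is a documented alternative the scheme
  deliberately does not default to, since the published description does
  not distinguish them.
* **lcwgs** — a seeded uniform random subset without replacement.  LCWGS is
  modelled as a random subset of true genotypes; read depths, genotype
  likelihoods and sequencing error are out of scope, consistent with how
  the benchmark derives its LCWGS panels from simulated variants.

The non-selected universe sites are the hidden imputation targets; observed
and hidden sets always partition the universe.

## Imputation engine

The built-in method is an unreduced Li–Stephens haplotype-copying HMM.
States are the K phased reference haplotypes; between adjacent scaffold
markers at distance `d` bp the chain switches with mass
`q = 1 - exp(-rho d / K)` spread uniformly over all K states (so
`P(stay) = 1 - q + q/K`), and emissions allow a copying error
`eps` (mismatch probability).  Defaults: `eps = 1e-3`;
`rho = 4 * Ne_eff * r` with `Ne_eff = 1,600` (the size of P1, the target
population's deme) and `r` the simulation's recombination rate — both
overridable per run.

Posteriors are computed by a scaled forward–backward pass (per-site
normalizers retained), chosen over log-space for vectorizability; the test
suite asserts equivalence against an independent log-space implementation
and against exhaustive path enumeration for small state spaces (to 1e-10).
A hidden site between scaffold markers m and m+1 is handled by exact
propagation: the forward vector at m advanced over the left sub-gap is
combined with the emission-weighted backward vector at m+1 advanced over
the right sub-gap.  Because the Li–Stephens kernel composes exactly over
abutting gaps, this equals the posterior of a silent state inserted into
the chain; flanking hidden sites use one-sided propagation.  The haploid
dosage is the posterior-weighted mean of the reference alleles at the
hidden site.

Targets are simulated with known phase, and each haplotype is imputed
independently (K states) rather than through a K^2 diploid HMM: genotype
dosage is the sum of the two haploid dosages.  This exercises the same
accuracy mechanics at far lower cost; an unphased-diploid mode is an
extension point, not a default.  Best-guess genotypes round dosage to the
nearest integer in {0,1,2} with ties rounding half to even — documented
because the allelic error rate depends on the rule.

Production imputers are variants of this same model with state-space
reduction (IBD-segment subsetting, genomic-block compression); those
internals are deliberately not reimplemented.  External tools plug in via
`external_imputer_roundtrip`, which writes scaffold/reference VCFs,
invokes a user command template and parses the imputed VCF back (GT for
best-guess, DS for dosage when present, with DS taking dosage precedence
and a logged warning on disagreement).  Missing executables, malformed
output and site-set mismatches raise distinct exceptions.  Because external
tools apply their own defaults (notably their internal effective population
size), absolute accuracies are not comparable across methods — only trends
are asserted anywhere in the package.

## Accuracy criteria and factor analysis

Per hidden locus, reliability is the squared Pearson correlation between
imputed and true 0/1/2 genotype vectors across target individuals, using
population (divide-by-n) moments; it is undefined (NaN) when either vector
is constant, and such loci are excluded from averages rather than scored
zero.  Reliability is computed on best-guess genotypes by default (a
dosage-based variant is available as the `-dosage` method suffix).  The
allelic error rate is `sum(|g_imp - g_true|) / (2 n_entries) * 100`, the
minimal unphased allele-mismatch count.  MAF bins default to edges
{0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5}, half-open with the final bin
closed at 0.5.

Factor influence is summarized two ways: the coefficient of variation
(population standard deviation / mean) of the factor-level marginal means —
the divide-by-n convention reproduces the published CV values exactly from
the published grid cells — and simple OLS regression of accuracy on factor
level, reporting the raw slope, the two-sided slope t-test p-value and the
standardized slope (the Pearson correlation).  The scale of the published
regression coefficients is not documented, so both raw and standardized
slopes are reported and neither is asserted against printed values.

Population relatedness uses a VanRaden genomic relationship matrix halved
to the kinship scale, `k(i,j) = sum_l (x_il-2p_l)(x_jl-2p_l) /
(2 sum_l 2 p_l (1-p_l))`, with block means, minima and maxima per
population pair.  The estimator behind the published kinship table is
unnamed, so its absolute values are treated as qualitative ordering targets
only (e.g. P3-P4 must be the most related pair).

## Scale profiles and problem sizes

Full scale (11,000 + 3 x 3,000 diploids, 10 Mb, 1,000 targets) is the
design's nominal size and is supported but cluster-sized.  The `desk`
profile — the package's default test and demonstration scale — uses 110
P1 + 3 x 30 diploids on 250 kb with 25 targets, chosen so a panel simulates
in ~2 s and a full 336-cell grid completes in minutes while every factor
contrast stays estimable.  Reference-size levels map onto the scaled panel
proportionally to the fraction of the full-scale pool they use, floored at
4 diploids and capped at the available non-target pool; the mapping is
monotone, so size-trend assertions remain meaningful.  At desk scale the
site density (~11-14 SNPs/kb) sits below the full-scale ~21 SNPs/kb
because segregating-site counts grow with the sample-size harmonic number;
the tests treat density only as an order-of-magnitude smoke check.

Acceptance-level statistical checks use: 5,000 replicates for the pairwise
TMRCA calibration (n = 2, one deme), 400 replicates for Watterson's
segregating-site count (n = 20 haploids, 1 Mb), three matched-seed desk
panels for the accuracy trend assertions, and 20 replicates for the
kinship ordering check.

## What passing tests do and do not show

The generator emulates the benchmark's simulated world: neutral biallelic
variants, perfect phasing, error-free genotypes, a single 10 Mb (or
scaled) chromosome, and a known demography.  Real data adds phasing error,
genotyping/sequencing error, selection and ascertainment bias that this
pipeline does not model, so passing tests validate the machinery and the
qualitative factor rankings — denser scaffolds, larger and closer reference
panels help — not absolute accuracy forecasts for a particular breeding
program.  Likewise the built-in HMM is the benchmark's method slot, not a
re-implementation of any production imputer, so absolute accuracy
tables from specific tools are reproduced only where they are arithmetic
consequences of their published grids (marginal means, CV rankings), never
re-estimated.

## Known limitations

* No gene conversion, selection, multi-chromosome genomes or forward-time
  simulation.
* LCWGS is a variant subset, not a read-level model (no depth/GL-aware
  imputation).
* The unreduced HMM scales as O(sites x K) per target haplotype; very large
  reference panels (K >> 1e3) are the domain of the state-space-reduced
  production tools.
* The exact published split topology and kinship estimator are unknown;
  both are configurable interpretations documented above.
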