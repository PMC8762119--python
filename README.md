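# imputesim

Simulation-based benchmarking of genotype imputation for SNP-array and
low-coverage whole-genome sequencing (LCWGS) marker panels.

## What this package is for

Before investing in a genotyping strategy, breeders and geneticists want to
know how imputation accuracy responds to the design knobs they control: the
size of the sequenced reference panel, the density of the typed marker
scaffold, how the markers are chosen (evenly tiled chip markers vs. a random
LCWGS-like subset), and how genetically distant the reference population is
from the study cohort.  `imputesim` answers this with a fully simulated,
fully reproducible pipeline:

1. **Simulate** phased sequence-resolution haplotypes for a four-population
   livestock (pig-like) demography — an ancestral population from which
   P1–P4 diverged with migration and bottlenecks — under the structured
   coalescent with recombination (a built-in Hudson-style ancestral
   recombination graph simulator; an msprime adapter is available behind the
   same interface).
2. **Ascertain** a variant universe (biallelic, MAF ≥ 0.01 in the target
   cohort) and select observed scaffold markers per scheme and density level
   (1–90 % of the universe).
3. **Impute** the hidden variants with a Li–Stephens haplotype-copying HMM:
   the target haplotype is modelled as a mosaic of K reference haplotypes,
   with switch mass `q = 1 − exp(−ρ d / K)` between markers at distance `d`
   and copying-error emissions ε.  Posteriors come from a scaled
   forward–backward pass; unobserved sites are filled in by exact HMM
   propagation between flanking markers.  External imputers (Beagle,
   Minimac, …) can be plugged in through VCF adapters.
4. **Evaluate** per-locus imputation reliability
   `r² = Cov(X,Y)² / (Var(X)·Var(Y))` between imputed and true 0/1/2
   genotypes, and the allelic error rate
   `er% = Σ|g_imp − g_true| / (2·n) × 100`, binned by minor-allele
   frequency; rank factors by the coefficient of variation of their
   level means and by OLS regression of accuracy on factor level.

The full factorial design — reference population (P1–P4) × panel size
(100–10,000) × density (1–90 %) × scheme (chip/LCWGS) × method — spans 336
scenarios.  Full scale (20,000 diploids × 10 Mb) is cluster-sized; the
bundled `desk` profile runs the same demography and contrasts at
workstation cost (200 diploids × 250 kb, reference sizes mapped
proportionally).

## Worked example

```python
from imputesim import ScenarioSpec, run_scenario
from imputesim.runner import DESK_PROFILE, simulate_profile_panel

panel = simulate_profile_panel(DESK_PROFILE, seed=11)
print(f"panel: {panel.n_individuals} diploids x {panel.n_sites} segregating sites")

res = run_scenario(ScenarioSpec("P1", 10_000, 0.30, "lcwgs", seed=5), panel)
print(f"observed {res.n_observed} / hidden {res.n_hidden} sites, "
      f"{res.n_reference} reference diploids")
print(f"mean reliability r2 = {res.mean_r2:.3f}")
print(f"mean allelic error  = {res.mean_error_rate:.2f}%")
```

prints

```
panel: 200 diploids x 2613 segregating sites
observed 462 / hidden 1078 sites, 85 reference diploids
mean reliability r2 = 0.986
mean allelic error  = 0.26%
```

i.e. with an LCWGS scaffold covering 30 % of the variant universe and the
largest same-population reference panel, imputing the remaining 70 % of
variants for 25 target individuals recovers genotypes almost perfectly at
this scale.  Swapping the reference population to the genetically distant
P4, or thinning the scaffold to 1 %, degrades `mean_r2` substantially —
`res.records` holds the per-locus values (MAF, r², error rate) behind these
aggregates, and `imputesim.runner.summarize` turns a list of scenario
results into reference-size × density matrices, factor-level marginal means
and coefficient-of-variation factor rankings.

A thin CLI mirrors the stages: `imputesim simulate | ascertain | impute |
evaluate | grid` (see `imputesim <cmd> --help`).

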