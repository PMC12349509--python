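# gburden

Deleterious-mutation burden analysis for plant germplasm conserved in
genebanks, with a forward-in-time simulator of selfing accessions under
storage mutation and regeneration purging.

## The problem

Seed accessions held in long-term cold storage accumulate deleterious
mutations — in storage and, more importantly, at every regeneration cycle
(growing stored seed to produce fresh seed, a bottleneck where selection and
drift act). Genebank managers and population geneticists need to quantify
that accumulation from sequencing data: which variants are deleterious, how
much load each accession carries, and how load relates to conservation
history (years since acquisition, years since the last regeneration, number
of regeneration cycles) and to RNA-level covariates (expressed gene counts,
expression level, RNA integrity number).

`gburden` implements that analysis as a reusable pipeline for RNA-Seq-derived
genotype data from selfing crops such as soybean, plus a generative simulator
so every stage — and the headline heterozygous-versus-homozygous accumulation
contrast — can be tested end to end without any sequencing data.

## The model

**Deleterious classification.** A SNP is a *dSNP* when its amino-acid
substitution is damaging by SIFT (score ≤ 0.05 at normal confidence) **and**
it falls at an evolutionarily constrained site (GERP++ rejected-substitution
score RS > 0). dSNPs are binned by RS into weakly (RS < 1), mildly
(1 ≤ RS ≤ 3) and highly (RS > 3) detrimental.

**Burden estimators.** For a sample genotyped at L dSNP loci with n_het loci
heterozygous and n_hom homozygous for the deleterious allele:

    B_het = n_het / (2L)      B_hom = 2 n_hom / (2L)      B_tot = B_het + B_hom

i.e. deleterious alleles carried per allele slot at deleterious loci. The
decomposition B_tot = B_het + B_hom holds exactly for every sample.

**Associations.** Each estimate is regressed (OLS, two-sided t-test on the
slope) on each conservation feature; the six per-sample estimates (three
burdens, expressed gene count, mean TPM, RIN) are screened pairwise; burdens
are compared across countries of origin by one-way ANOVA.

**Simulator.** Accessions evolve by single-seed descent: storage-phase
mutation per year, per-generation gametic mutation at each regeneration,
Mendelian selfing segregation, and viability selection
w = Π (1−s_i)^[hom] (1−h·s_i)^[het]. Because a site homozygous in the parent
is homozygous in every selfed offspring, purging acts only at segregating
sites — fresh strongly-selected mutations therefore accumulate as
heterozygotes (rising with regeneration cycles and saturating), while the
homozygous load stays at the standing "legacy" level. That is exactly the
empirical signature the analysis is designed to detect.

## Worked example

Simulate a 190-accession collection under the default (calibrated)
parameters, classify, and estimate burdens:

```python
from gburden import (SimConfig, generate_dataset, classify_deleterious,
                     compute_burdens, recover_parameters)

sim = generate_dataset(SimConfig(seed=42))
dset = classify_deleterious(sim.annotation)          # SIFT<=0.05 & RS>0
burden = compute_burdens(sim.variant_set, dset)
print(burden[["B_tot", "B_het", "B_hom"]].describe().round(4))
print(recover_parameters(sim).to_frame().to_string(index=False))
```

prints (L = 581 segregating deleterious loci in this replicate):

```
       B_tot   B_het   B_hom
mean  0.0449  0.0127  0.0322
std   0.0069  0.0037  0.0054
min   0.0241  0.0017  0.0172
max   0.0620  0.0215  0.0465
                          check     slope      p_value  passed
    B_het_increases_with_cycles  0.000798 1.231829e-13    True
    B_tot_increases_with_cycles  0.000677 1.420518e-03    True
         B_hom_flat_with_cycles -0.000121 4.776432e-01    True
RIN_declines_with_storage_years -0.057673 1.192849e-29    True
```

Per-sample total burden averages ≈ 0.045 deleterious alleles per allele slot,
heterozygous and total burden rise significantly with completed regeneration
cycles (positive slopes, tiny p-values), homozygous burden shows no cycle
trend, and RIN declines with years since the last regeneration — the
accumulation signature the pipeline recovers from its own generative model.

The same flow is available from the shell:

```bash
gburden simulate --seed 42 --out simdir/
gburden filter --vcf simdir/genotypes.vcf --min-dp 0 --min-qual 0 --out filtered.vcf
gburden classify --ann simdir/annotation.tsv --out dsnp.tsv
gburden burden --vcf filtered.vcf --dsnp dsnp.tsv --out burden.tsv
gburden run --config run.yaml     # or everything at once
```

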