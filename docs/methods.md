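# Methods

This note records the models, parameter choices and numerical conventions
behind `gburden`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Input filtering (`variant_io`)

Raw VCF records pass four site/genotype rules, attributed in a fixed ledger
order so attrition counts are deterministic: (1) non-SNP (indel) records,
(2) multi-allelic sites, (3) site quality below `min_qual` (default 20; an
absent QUAL fails the rule, and `min_qual = 0` disables it), (4) genotype
calls with FORMAT DP below `min_dp` (default 10) are set missing and any
site retaining a missing call is dropped when completeness is required.
`min_dp = 0` disables the depth rule so GT-only VCFs (including this
package's own filtered output, which carries no DP) remain usable. Each
dropped site counts against the *first* rule it fails; a joint filter (as a
single vcftools-style invocation applies) yields the same surviving set,
only the attribution differs. Coordinates are 1-based; chromosome labels
are kept verbatim and compared case-sensitively; phased and unphased calls
are equivalent; half-calls ("./1") are missing. Filtering is idempotent.

Accession metadata accepts calendar years (converted against a reference
assay year) or elapsed years directly, and enforces: years since last
regeneration ≤ years since acquisition; zero regenerations implies the two
are equal; RIN ∈ [1, 10].

## Deleterious classification (`annotate_classify`)

A variant is deleterious iff SIFT ≤ 0.05 ∧ confidence is not low
∧ RS > 0; a variant lacking either score is never deleterious (sites
outside the constrained-region RS track are unclassifiable, not weakly
constrained). Two boundary conventions are deliberate and exposed as knobs:

* **SIFT threshold inclusive (≤ 0.05)** — the SIFT convention ("0.05 or
  less is deleterious"); the strict variant is one flag away (`sift_max`).
* **Severity bins weak RS < 1, mild 1 ≤ RS ≤ 3, high RS > 3** — the closed
  mild interval makes the three bins partition every positive RS value,
  consistent with the reference tally whose three categories sum to the
  dSNP total.

Consequence tallies run over a closed 16-class most-severe-consequence
vocabulary; the loss-of-function aggregate sums the three stop\_, three
splice\_ and start_lost classes. Unknown labels are a hard error naming the
label.

## Burden estimation (`burden_stats`)

The deleterious allele is operationalised as the alternate allele of the
SIFT-scored substitution; no outgroup polarisation is attempted
(reference-genome polarisation bias is acknowledged), and an explicit
per-site deleterious-allele column is accepted as an alternative convention.
The denominator L is the analysis-wide dSNP count, not a per-sample callable
count — the input matrix is complete by construction. Fixed dSNPs stay in L
(they add a constant to every sample's homozygous burden) and are reported
via the MAF spectrum's `fixed` flag. B_tot is computed as B_het + B_hom so
the three-way decomposition holds to the last bit, not merely to rounding.

MAF = min(p, 1−p) of the alternate-allele frequency; band flags at
MAF ≤ 0.01 and ≤ 0.05 are inclusive. Chromosome summaries divide by the
expected chromosome count (default 20) even when a chromosome carries no
variant; labels outside the expected range tally under "other" with a
warning.

## Expression summaries (`expression_rin`)

"Expressed" means TPM strictly above the floor, default 0 — a
presence/absence notion; no published TPM cutoff exists for these data, so
the floor is exposed (`tpm_floor`). The per-sample mean TPM averages over
that sample's *expressed* genes only and is undefined (NaN, flagged) for a
sample expressing none.

## Association battery (`association`)

Simple OLS per test (scipy's `linregress`; equivalent to R's `lm` for one
predictor), two-sided t-test on the slope. Significance bands: p < 0.05
significant; 0.05 ≤ p < 0.10 "marginal" — the marginal band is a package
convention (configurable), chosen as the conventional reporting band.
No multiple-testing correction is applied to the primary labels, matching
per-test α reporting; a Benjamini–Hochberg column is emitted alongside,
clearly labelled an extension. One-way fixed-effects ANOVA across groups
with at least `min_group_n` members (default 3 — the smallest size with a
within-group variance worth pooling); excluded groups are visible because
`groups_used` is always reported. The full battery is 33 tests: 3 burdens ×
3 conservation features, 15 unordered pairs of the six estimates, and
3 expression/RIN estimates × 3 features.

## The conservation simulator (`synthetic_data`)

### Generative model

Per accession, by single-seed descent from acquisition to assay:

* **Storage**, each year: every reference allele copy at a mutable site
  mutates with probability `mu_storage` (hom_ref → het at ≈ 2μ, het →
  hom_alt at μ). Irreversible.
* **Regeneration**, at scheduled years: a selfed seed is drawn — het sites
  segregate 1/4 : 1/2 : 1/4, transmitted reference alleles mutate at the
  per-generation rate `mu_regen` — and survives with probability
  w = Π (1−s_i)^[hom] · (1−h·s_i)^[het]. One surviving seed continues the
  lineage (distributionally identical to growing `n_regen` survivors and
  picking one, since survivors are i.i.d.). A pooled mode (accession =
  `n_regen` plants, each seed selfing from a random parent plant) is
  provided for contrast.

Two structural facts shape the defaults. First, regeneration is a full
plant generation — vastly more DNA replication than −18 °C storage — so the
per-cycle gametic input dominates the per-year storage input. Second, a
site homozygous in the parent is homozygous in every selfed offspring:
within-family selection cannot purge fixed load, only bias segregation at
het sites. Deleterious-capable sites therefore carry one of two fitness
classes:

* **legacy** (fraction `legacy_frac` = 0.12): standing variants present at
  acquisition, at Beta-distributed frequencies (mean 0.30) — by
  survivorship their fitness cost is attenuated (`s_legacy` = 0.02). They
  supply the static homozygous load and, under an infinite-sites rule,
  receive no new mutation.
* **active** (the rest): empty at acquisition, populated by new mutations,
  strongly selected (`s` = 0.99, `h` = 0.02) so the fresh homozygote is
  nearly inviable.

Functional severity (the RS bin) is assigned independently of fitness
class: deleterious-to-gene-function does not imply proportionally
deleterious-to-plant-fitness.

### Calibration of the defaults

With per-cycle het input m = 2·`mu_regen`·n_active and per-cycle het
retention P(het|survive) = ½(1−hs)/Z (Z the mean offspring fitness at a het
site ≈ 0.74, giving retention ≈ 0.66), the heterozygous equilibrium is
m/(1−0.66) ≈ 3m. Defaults are set so the equilibria reproduce the reference
seed assay's per-sample burden means (B_het ≈ 0.015, B_hom ≈ 0.036,
B_tot ≈ 0.051 at L = 588): `mu_regen` = 5.8 × 10⁻³ per allele per cycle
(n_het* ≈ 17.6) and legacy load 0.12 · 588 · 0.30 ≈ 21 homozygous loci.
These per-site rates are deliberately inflated by orders of magnitude over
per-base biological rates so that a few hundred loci carry a desk-scale
signal; they make no claim of per-site realism. Schedules draw acquisition
years uniformly over 1972–2004 (18–50 years before a 2022 assay), completed
cycles 0–10 rising with time in the bank, and the last regeneration 4–25
years before assay — inducing the cycles-by-age correlation a real
collection shows. RIN = 8.6 − 0.06 · (years since last regeneration) + noise;
expressed gene count and mean TPM are linked to true total burden and RIN
with signs (−, +) and (+, −) respectively, so the pairwise screen's
correlation structure is reproduced.

### What the simulator does and does not emulate

It emulates: a complete biallelic genotype matrix over segregating sites
(non-segregating sites are dropped, as a SNP caller would); an annotation
table whose deleterious sites satisfy the SIFT∧RS rule exactly, with
tolerated / RS-negative / low-confidence / non-missense decoys exercising
every classifier branch; L-shaped allele-frequency spectra (rare fresh
mutations plus a minority of common legacy variants); metadata within the
study's covariate ranges; and burden/expression/RIN correlation structure.
It does not emulate: sequencing error or missingness (genotypes are true),
linkage (sites are independent, matching the single-site burden statistics),
invariant-heterozygous artefact sites, outcrossing, within-accession seed
heterogeneity at assay (one seed is assayed), or RNA-degradation
biophysics. Passing recovery tests therefore shows the *pipeline* detects
the accumulation signature when the generative assumptions hold — not that
real collections satisfy those assumptions.

### Numerical choices

Viability selection is rejection sampling over candidate seeds (batch 256,
cap 200,000 candidates per survivor; breach is a hard error advising weaker
selection, never silent truncation). Fitness factors from the parent's
locked homozygous load are constant across its offspring and cancel in the
conditional distribution of the surviving seed, so acceptance uses fitness
relative to the best offspring — without this the sampler wastes draws by
exactly that constant and the cap becomes reachable at the calibrated
defaults. Fresh-mutation counts are drawn per candidate as binomials and
placed on uniformly chosen sites after acceptance (exactly equivalent to
per-site Bernoulli draws, since selection coefficients are constant within
a fitness class). All randomness flows from one `numpy` Generator seeded by
`SimConfig.seed`; identical configs give byte-identical outputs.

## Published-count fixtures (`calibration`)

The tally, classification, MAF-band and chromosome-mean checks run on
synthetic fixtures that realise the reference assay's printed marginal
counts exactly (58,548 SNPs across 16 classes; 6853 SIFT-deleterious of
which 941 low-confidence; 588 combined-rule dSNPs split 45/477/66;
507/123 MAF-band members; 1344 invariant-het sites). They verify the
arithmetic mechanics against the published summaries, not the underlying
variants, which are not reconstructable from printed tables.

## Problem sizes

The test suite and the acceptance script use: 10,000-replicate Monte-Carlo
nulls for the regression and ANOVA type-I rates; a 1000 × 600 random matrix
for the burden-estimator oracle; 10,000 one-step regenerations for the
neutral selfing expectation; and 50 independent full-scale (190 accessions,
588 deleterious-capable sites) simulated collections for the
accumulation-signature recovery rates. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances (e.g. ±0.01 on a
0.05 rejection rate at 10,000 reps, SE ≈ 0.002).

## Known limitations

* Burden polarisation assumes the alternate allele is the derived
  deleterious allele; reference-genome bias is not corrected.
* The ledger's rule order is a convention; only the order-free surviving
  set is comparable across tools.
* The country-group ANOVA's group-selection rule (minimum group size) is a
  package convention; different choices change which groups enter F-tests.
* The simulator's single-seed mode makes `n_regen` irrelevant to the
  assayed genotype's distribution (survivors are i.i.d.); purging strength
  is governed by s and h, not by the regeneration sample size, except in
  pooled mode.
* Mutation-rate and selection defaults are calibrated to reproduce
  collection-level burden summaries, not measured per-base rates.
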