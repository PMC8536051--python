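# Methods

## Scope and data model

The pipeline operates on four inputs: a GWAS-catalog association export
(tab-separated, `SNPS` / `STRONGEST SNP-RISK ALLELE` / `CHR_ID` /
`CHR_POS` columns), a multi-sample VCF of biallelic SNVs with a
sample→population map (1000 Genomes phase 3 style, GRCh37, 1-based
coordinates throughout), an optional published frequency table for a
cohort whose genotypes are not distributed (KRGDB dialect: variant, REF,
ALT, ALT frequency, sample count), and a population phenotype table
(mean 25(OH)D3 in ng/mL, latitude in degrees).

Every frequency in the package is an *effect-allele* frequency. The
catalog curation stage resolves each SNP's effect allele against the
panel's REF/ALT pair once; downstream code never re-reasons about allele
orientation.

## Catalog curation

Associations are split on the catalog's multi-SNP delimiters (`;` for
haplotype entries, ` x ` for interactions) into one record per rsID and
logged; rows without a parseable rsID are dropped with a warning.
Duplicate rsIDs keep the first occurrence in file order — the choice is
immaterial downstream (only the rsID and allele survive) but must be
deterministic to be auditable.

Effect-allele resolution, in order: exact match of the reported risk
allele against the panel alleles; reverse-complement match for
non-ambiguous SNPs (an opposite-strand report); panel minor allele when
the catalog reports `?` (risk alleles in this trait's catalog entries are
predominantly minor alleles, so the minor-allele fallback is the best
available prior, and such records are tagged `minor_allele_fallback` so
they can be excluded in sensitivity analyses). A/T and C/G variants read
identically on both strands, so they are accepted on exact match only and
flagged. A stated allele matching neither panel allele nor its complement
drops the record with a warning — never silently kept.

Records lacking a chromosomal position are retained if the rsID resolves
in the panel; position is informational here. Trait filtering is assumed
done by the catalog export; an optional substring filter on
`DISEASE/TRAIT` is provided.

## Frequencies

Dosages count copies of the effect allele (ALT count, or 2 − ALT count
when the effect allele is REF). Missing genotypes shrink the denominator;
no imputation happens at the frequency stage. The global background pools
all samples of the base panel. A frequency-only cohort (e.g. the Korean
reference cohort) is compared against that background but never pooled
into it, since it is external to the panel.

Counts reconstructed from published frequencies use half-up rounding of
`eaf × 2n`. This matters: at the extreme frequencies this analysis
shortlists, Fisher p-values are sensitive to a one-allele difference, and
banker's rounding would bias reconstructions of x.x5 frequencies.
Reconstruction from printed (2–3 digit) frequencies limits the accuracy of
recomputed statistics to a few percent in |log10 p|, which is why
reference-table checks use sign agreement, rank correlation and a ±15%
band rather than exact values.

## Signed Fisher enrichment

Each (SNP, population) cell tests the 2×2 table of effect/other allele
counts in the population against the background. The two-sided p-value
sums hypergeometric point probabilities not exceeding the observed
table's. Implementation choices:

- **Log space end to end.** Point probabilities are computed as log-gamma
  expressions and summed with log-sum-exp; the statistic is exact in
  log10 units at any magnitude. Population-scale tables routinely reach
  |log10 p| of 100–300, where any probability-space computation
  underflows. An optional saturation cap reproduces pipelines that bottom
  out near the double-precision underflow threshold (the packaged
  reference table shows a repeated ceiling of 312.61, the signature of
  such a computation); the default applies no cap.
- **Tie tolerance.** A table is included in the two-sided sum when its
  log point probability is ≤ the observed one plus `log1p(1e-7)`,
  protecting exactly-tied tables from floating-point exclusion. Against
  exact rational enumeration over all 2×2 tables with both group sizes
  ≤ 30, the worst relative error is below 1e-13, and the tolerance admits
  no strictly-more-probable table in that range.
- **Degenerate margins** (pooled sample monomorphic) give p = 1 and a
  zero statistic; when every table in the support ties the observed one,
  p is returned exactly as 1.
- **Sign convention.** +|log10 p| when the population frequency exceeds
  the background, −|log10 p| below, exactly 0 on a tie, so
  sign(s) = sign(EAF_pop − EAF_bg) whenever the frequencies differ.
- **Background mode.** The default tests each population against the full
  pooled panel (inclusive), matching how the statistic is usually
  reported alongside a global reference frequency; a complement mode
  subtracts the tested population's counts first and falls back to
  inclusive for cohorts that are not a subset of the panel. No
  multiple-testing correction is applied by default (the classification
  threshold is p < 0.05); Bonferroni-style adjustment can be layered on
  by callers via the alpha parameter.

Classification partitions SNPs into enriched (p < α, s > 0), depleted
(p < α, s < 0) and comparable (p ≥ α); the extreme subset collects
|s| > 100, the criterion behind the published 29-SNP shortlist.

## Population clustering

Columns of the signed matrix are clustered agglomeratively with
**correlation distance (1 − Pearson) and complete linkage** by default.
The magnitude of a signed log10 p grows with cohort size — a 1722-sample
cohort dwarfs 350-sample groups in Euclidean distance and gets isolated
at the root regardless of its enrichment pattern. Correlation distance
compares the patterns themselves; on the packaged reference matrix it
recovers the expected root bipartition ({EUR, AMR, SAS} vs
{AFR, EAS, KOR}) where Euclidean distance does not. Euclidean and any
other scipy metric remain available as options. Ties in leaf order follow
input order; NaN cells are imputed as 0 (no evidence) with a warning.

## Composite GRS

GRS = Σ X_i / (2I), unweighted by design: per-allele effect sizes for
25(OH)D3 are unstable across ancestries, and weighting would import that
instability into cross-population comparisons. Anchors: 1 for a
homozygous effect-allele carrier at every SNP, 0 for a complete
non-carrier, 0.5 in expectation under uniform random dosages.

Missing dosages are replaced by 2·(population EAF at that SNP), keeping
the denominator 2I; a strict mode refuses incomplete samples instead.
With complete genotypes the cohort mean equals the mean per-SNP EAF
exactly (an identity tested to machine precision), which justifies the
frequency-form score used when only published frequencies exist.

The two-phase concordance filter excludes SNPs with
|freq_total − freq_phase2| > 0.10 — an absolute frequency difference,
strict inequality, so a difference of exactly 0.10 is retained. The
absolute reading is the common usage for frequency QC thresholds.

## Association stage

Ordinary least squares throughout (statsmodels). `linear_fit` reports
coefficients, standard errors and R² = 1 − SSres/SStot; a constant
predictor is an error, a constant response yields R² = 0 with a warning.
The concentration-vs-GRS "U curve" is modelled as an OLS parabola — the
simplest form with curvature; nothing in the data model pins down a
functional form beyond that. The difference analysis subtracts a
configurable reference population (default EUR) from every other
population and regresses Δconcentration on ΔGRS and on Δlatitude
separately; differencing makes both fits invariant to constant shifts of
either variable. With few populations these R² values carry large
sampling variability and should be read comparatively, not absolutely.

## Synthetic data generator

Population frequencies follow the Balding–Nichols model: around ancestral
frequency p0 ~ Uniform(0.05, 0.95), a population at differentiation F
draws Beta(p0(1−F)/F, (1−p0)(1−F)/F), with mean p0 and variance
F·p0(1−p0); F acts as F_ST. A two-level clade tree draws an intermediate
clade frequency first (clade F = 0.2 by default) and then populations
within the clade (F = 0.02), giving correlated enrichment patterns within
clades and clean separation between them. Genotypes are Hardy–Weinberg
binomial draws; the two-phase simulator subsamples alleles
hypergeometrically and injects a 0.15 frequency shift at a chosen number
of SNPs so the concordance filter has known positives.

Default conditions mirror the real study design: six cohorts labelled
like the continental groups plus the Korean cohort at the published sizes
(AMR 347, AFR 661, EAS 504, SAS 489, EUR 503, KOR 1722), 320 SNPs, clades
{EUR, AMR, SAS} and {AFR, EAS, KOR}. Phenotypes follow
concentration = β0 + β_grs·GRS + β_lat·latitude + ε with defaults
β0 = −75 ng/mL, β_grs = 200 ng/mL per unit score, β_lat = −0.05 ng/mL per
degree, σ = 0.3 ng/mL: cohort composite scores differ by only a few
hundredths while real population concentrations differ by 10–15 ng/mL, so
a realistic slope on GRS is of order 10²–10³, and the defaults place the
generator in the regime the analysis studies — genetic differences
dominating latitude.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, selection, migration or any demographic history beyond the
two-level clade tree, genotyping error, and the confounding of latitude
with ancestry that real cohorts have. Passing tests on synthetic data
therefore demonstrate the statistical machinery (exactness, identities,
recovery under the generating model), not robustness to real-data
artifacts.

All randomness descends from a single root seed through named substreams
(frequencies / genotypes / phenotypes / subsampling), so stages are
independently regenerable and full runs are byte-reproducible.

## Problem sizes in the test suite

The suite runs the Fisher sweep exhaustively over all 2×2 tables with
group sizes ≤ 30 (≈ 245,000 tables) against an exact rational oracle;
parameter recovery uses 200 replicates of 20 populations × 100 SNPs;
clade recovery uses 100 replicates of 6 populations × 60 SNPs at 100
individuals per population; identity checks use 100 random cohorts. These
sizes give stable statistics while keeping the whole suite under a
minute of compute.

## Known limitations

- The ±2·SE slope-coverage check in the test suite has nominal coverage
  P(|t₁₈| ≤ 2) ≈ 93.9% at 20 populations, not 95%; observed coverage
  fluctuates accordingly across seed sets. The t-based 95% interval
  (2.101·SE) is the calibrated one.
- Reconstructed counts from printed frequencies inherit printing
  precision; recomputed statistics are validated by sign, rank and
  percentage band, not exact value.
- The pipeline handles biallelic SNVs only; multi-allelic records and
  indels are skipped with warnings.
- Strand-ambiguous (A/T, C/G) variants cannot be rescued by complement
  matching and are accepted on exact match only; palindromic SNPs with
  allele-frequency near 0.5 remain a residual mis-orientation risk, as in
  any harmonization without explicit strand metadata.
- No liftover: coordinates are taken as GRCh37 throughout.
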