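# Methods

This note documents the statistical machinery of `hostmicrobe`: what each
stage computes, the assumptions behind it, the defaults and why, and what the
synthetic cohort generator does and does not emulate.

## Problem setting

The package analyses paired data from one human cohort: host genotypes
(a donor × variant alternate-allele dosage matrix) and shotgun-metagenomics
microbiome profiles (species-level relative abundances and metabolic-pathway
abundances, per sample, per body site), plus donor metadata (sex,
self-reported ethnicity, sample collection site). The questions it answers:

1. Does high-level host genetic structure (ancestry, summarized by genotype
   principal components) covary with microbiome composition at a body site?
2. Are specific pathway superclasses enriched among the most
   genetically-covarying features?
3. Are genetically related donors' microbiomes more similar than unrelated
   donors'?
4. Do individual common variants associate with individual microbial
   features, either in targeted candidate tests or genome-wide?

## Genotype core

**Variant QC.** Common well-called variants are selected by strict
inequalities MAF > 0.05 and call rate > 0.95 (the conventional
common-variant definition). The filter recomputes MAF and call rate from the
dosage matrix, is idempotent, and never reorders donors.

**PCA.** Missing dosages are mean-imputed per variant (the PLINK convention);
each variant column is centred by 2p̂ and scaled by sqrt(2p̂(1−p̂)), the
variance of a binomial(2, p̂) draw, so every variant contributes equal
expected variance. Scores are the top-k left singular directions scaled by
their singular values; `variance_fraction` is each component's share of the
total variance of the standardized matrix. The sign of each component is
fixed by requiring a nonnegative loading sum, making output deterministic.
Monomorphic or all-missing variants are dropped with a warning; requesting
more components than the matrix rank is an error.

**Kinship.** The KING-robust estimator is computed per donor pair over sites
non-missing in both:

    phi = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa^(i) + N_Aa^(j))

where N_Aa,Aa counts sites heterozygous in both donors, N_AA,aa sites with
opposite homozygotes, and the denominator sums the per-donor heterozygote
counts. Among the published KING variants we use the sum-denominator
("kinship") form: its expectation equals the kinship coefficient for
non-inbred pairs, and duplicate genotypes give exactly 0.5. A
minimum-denominator variant exists and is slightly more robust to inbreeding
asymmetry; the sum form was chosen for its exact-duplicate property and
unbiasedness, and the difference is negligible for the pair types simulated
here. Pairs with no heterozygous sites have undefined phi and are flagged.

Relatedness degree uses the half-open kinship intervals [0.0442, 0.0884) for
third degree, [0.0884, 0.177) for second degree, [0.177, 0.354) for first
degree, and ≥ 0.354 for twins/duplicates; below 0.0442 is unrelated. The
published ranges leave phi = 0.354 itself unassigned ("[0.177, 0.354)" vs
"> 0.354"); we assign the boundary to the twin class — a measure-zero choice
that only matters for exactly-boundary estimates.

## Microbiome feature preparation

Order of operations: **average replicates → prevalence filter →
log-transform**. Replicate samples of the same donor and body site are
averaged arithmetically on the raw abundance scale (averaging is not defined
on log values). Prevalence (presence = abundance > 0, no detection floor —
upstream profilers already threshold) is then computed at the donor level;
a flag restores sample-level filtering for sensitivity analyses. Species are
kept when present in **at least** 25% of donors (non-strict); pathways when
present in **more than** 75% (strict). Finally, species relative abundances
are log10-transformed with a pseudocount of 1e-5 (so absent species map to
−5, below the typical detection scale of relative abundances), while pathway
reads-per-million values are log10-transformed **present-only**: zeros become
missing and are excluded pairwise from downstream model fits, reflecting that
pathway zeros are rare and closer to detection failures than true absences.

Bray-Curtis dissimilarity BC = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) is computed on
untransformed relative abundances over the whole profiled community
(pre-filter), since the distance is meant to describe community composition,
not the tested feature subset. Similarity is 1 − BC.

## Permutation variance-explained framework

For each prepared feature y (log10 scale), an OLS fit on an intercept plus
the first five genotype PCs yields R² = 1 − SS_res/SS_tot. Five components
is where ancestry signal concentrates in multi-ethnic human cohorts; features
need ≥ 8 complete cases and nonzero variance, otherwise they are skipped.

The null distribution shuffles donor labels B times (default B = 10,000).
Each permutation applies **one shared shuffle to the entire feature table**:
this preserves the inter-feature correlation structure (strong under
compositionality), which is what makes the site-level statistic — the
across-feature mean R² — exchangeable under the null. The site Z-score is
(observed mean − permutation mean)/permutation SD; empirical p-values use the
add-one estimator

    p = (1 + #{permuted ≥ observed}) / (B + 1)

bounded below by 1/(B+1) (≈ 1e-4 at B = 10,000) and counting ties as
exceedances. The add-one form avoids impossible zero p-values; at four
decimals it matches the plain proportion for any non-extreme statistic.
Per-feature p-values are BH-adjusted across the features of one table.

**Enrichment.** Pathways are ranked by decreasing R² (ties broken by name for
determinism). For a superclass with k members at normalized ranks
r₍₁₎ ≤ … ≤ r₍ₖ₎ (rank/n), the robust-rank-aggregation score is
ρ = min_j P(Beta(j, k−j+1) ≤ r₍ⱼ₎) — the most surprising order statistic
under uniform ranking — and the reported p-value is min(1, k·ρ), a Bonferroni
correction over the minimum. This construction is conservative
(super-uniform under random rankings, verified by simulation). A one-sided
Wilcoxon rank-sum alternative (`method="wilcoxon"`) is exposed for
sensitivity.

## Variant–feature association

**Encoding.** Additive = dosage 0/1/2; recessive = 1 for alternate
homozygotes else 0 (a single working copy suffices for dominant-functional
loci such as a secretor gene). Missing propagates.

**Linear model.** Transformed feature abundance is regressed on the encoded
genotype with sex, ethnicity, and collection site as one-hot covariates
(first level as reference). Computation is Matrix-eQTL style: y and g are
residualized on [intercept | covariates], r is the Pearson correlation of
residuals, t = r·sqrt(df/(1−r²)) with df = n − rank(design) − 1, and the
two-sided Student-t tail gives p. This is algebraically identical to the OLS
coefficient test on g in the full design (verified against a normal-equations
oracle to 1e-10). Complete cases are selected per (variant, feature) pair;
genotypes constant after deletion are skipped; rank-deficient covariates are
an error naming the collinear columns.

**Targeted screens** test one candidate variant against every feature of a
body site, by dosage regression or by a two-sample t-test between alternate
homozygotes and everyone else (Student's pooled-variance form by default —
the classical "t test" — with a Welch option), then BH-adjust across the
screen's features.

**Genome-wide scan** restricts to variants with MAF > 0.1 computed on the
body site's donors (optionally further restricted to a user-supplied variant
panel), tests every (variant, feature) pair, and records the exact test count
for Bonferroni control (threshold = alpha / n_tests). Post-processing:

- *Clumping*: per feature, position-sorted associations are grouped greedily,
  starting a new group when the gap to the previous variant exceeds
  10,000 bp (a gap of exactly 10,000 stays joined); each group is represented
  by its minimum-p member, ties to the smaller position.
- *Gene annotation*: genes whose interval (1-based inclusive; BED converted
  at the file boundary) lies within 50 kb of the variant.
- *Q-Q diagnostics*: observed vs expected −log10 p with plotting positions
  (i − 0.5)/m and a through-the-origin slope as an inflation summary.

## Relatedness vs microbiome similarity

Every profiled donor pair at a body site is grouped: **relatives** (kinship
≥ 0.0442, i.e. third degree or closer — taking precedence over ethnicity),
else **same ethnicity** / **different ethnicity** by the metadata labels.
Similarity is 1 − Bray-Curtis on donor-averaged raw relative abundances.
The headline statistic is a pooled two-sample t-test of relatives against all
other pairs; the same-vs-different ethnicity mean gap is reported
descriptively. With fewer than two relative pairs only the group means are
reported. Caveat, by design: pairwise similarities sharing a donor are not
independent, so the t-test p-value is approximate; a permutation test
respecting pair dependence is out of scope.

## Synthetic cohort generator

The generator produces complete cohorts so every stage is testable without
data downloads. One global seed expands into fixed per-stage streams
(genotypes, pedigree, microbiome, metadata), so a config reproduces the
cohort bit-for-bit.

**Genotypes** follow the Balding–Nichols model: per variant, an ancestral
frequency p₀ ~ Uniform(0.05, 0.95); per population, a drifted frequency
~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with divergence F (default 0.1, the scale
of continental human differentiation); per donor, a Binomial(2, p_pop) draw.
Variant positions are uniform on one synthetic 50-Mb chromosome — enough to
exercise 10-kb clumping and 50-kb annotation without a real map. Default
cohort structure mirrors a typical body-wide metagenomics reference cohort:
300 donors, five ancestry groups
with weights (0.71, 0.06, 0.09, 0.11, 0.03), two collection sites, and
twelve cryptic related pairs (eleven first-degree, one third-degree).

**Relatives** are planted by overwriting consecutive donor pairs within the
largest population: twins duplicate a genotype; parent–offspring transmit one
Mendelian allele plus one population allele; half-sibs share one simulated
mother; first cousins descend from a shared grandparental couple in a
four-founder pedigree. Variants carrying planted single-variant effects have
their population frequencies clipped into [0.2, 0.8]: these effects emulate
validated common-variant associations (e.g. a secretor variant at MAF 0.41),
and a drifted rare variant would silently fall below downstream MAF filters.

**Microbiome profiles** are log-normal latent variables: per feature, a donor
baseline Normal(μ_f, σ_f) with μ_f ~ Uniform(−4, −1) log10 relative abundance
for species (Uniform(1, 4) log10 RPM for pathways) and σ_f = 1.0 log10 units
(inter-individual spread typical of gut taxa). Planted effects add
slope × standardized donor PC score and/or slope × encoded genotype to the
latent log10 abundance — the same scale the analysis models. Replicates add
within-donor noise σ_rep = 0.1 (repeat samples of a donor are far more
similar than two donors; within-donor technical-plus-temporal variance is
rarely quantified, so σ_rep is a free parameter chosen an order of magnitude
below σ_f). Zeros are planted
independently per entry with probability zero_inflation × (1 − π_f), where
π_f ~ Uniform(prevalence_range) is the feature's presence propensity
(defaults: zero_inflation 0.3, prevalence_range (0.3, 0.95), giving the mix
of core and patchy taxa seen in real profiles). Species rows are then
renormalized to relative abundances; pathway values stay on the RPM scale.
A planted feature zeroed out everywhere is recorded as a warning in the truth
output.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: linkage disequilibrium beyond pedigree sharing,
body-site-specific ecology, taxon–taxon interactions beyond compositional
closure, read-level noise, and any real genotype–microbiome coupling other
than the planted effects. Calibration results (uniform null p-values, power
against planted effects) validate the machinery, not biological effect sizes.

## Numerical choices and degenerate inputs

- Permutations, PCA, and all simulations are seeded; identical seeds give
  byte-identical outputs (tested end-to-end through the CLI).
- Empirical p-values: add-one form, ties count against the observation.
- PCA signs fixed by nonnegative loading sums; eigen-problems solved by SVD.
- Genotype-in-covariate-span detection uses a 1e-10 relative residual-norm
  tolerance.
- Zero p-values entering Q-Q diagnostics are clipped to the smallest positive
  float with a warning.
- Degenerate contracts: constant features and constant genotypes are skipped
  with warnings, never silently zero-filled; all-zero abundance profile pairs
  make Bray-Curtis an error; empty filter results warn.

## Problem sizes used in the shipped checks

Simulation-based checks run at desk scale chosen to keep the estimator
behaviour in its asymptotic regime while staying quick: 10,000 variants for
kinship recovery (classification needs the estimator SD ≈ 0.005, well under
the 0.044 class width), 200 donors × 200 features × 500 permutations for
null calibration, 20 seeded repetitions for power checks, and a few hundred
variants for scan calibration. The analysis code itself is size-agnostic.
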