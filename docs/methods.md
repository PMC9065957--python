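# Methods

Statistical model, parameter choices, and numerical details for `methfam`.

## Data model

Input is per-CpG bisulfite counts: for site *i* and sample *j*, a coverage
`n_ij` and methylated count `m_ij` (bedGraph, 0-based half-open, or
methylKit, 1-based, accepted; positions are stored 0-based and sorted per
chromosome). Counts are modelled as beta-binomial: the per-read
methylation probability varies around the sample's true level `p_ij` with
overdispersion `phi`, giving

```
Var(m_ij / n_ij) = p(1-p) * (1 + (n_ij - 1) * phi) / n_ij
```

`phi = 0` recovers the binomial; replicate WGBS data typically sit near
`phi ≈ 0.05–0.2`.

## SNP masking and coverage filtering

C/T variants are removed by interval subtraction against a BED of known
SNPs (merged intervals + binary search; exact). The coverage filter keeps
a CpG when between `min_cov = 5` and `max_cov = 80` reads are present in
at least 80% of samples — the upper bound removes collapsed repeats, the
lower bound unstable proportions. "80% of n samples" is the integer
ceiling (44 of 54). Downstream matrix analyses (RDA, clustering) further
restrict to complete cases within the sample set analysed.

## Smoothing and site-level tests

Counts are pooled over a centred 500 bp window (total width) per sample:
`N_ij = Σ n`, `M_ij = Σ m` over sites within 250 bp on the same
chromosome. Methylation is locally correlated at this scale, so pooling
raises effective coverage without erasing DMR-scale signal.

Each site is tested by weighted least squares of the
variance-stabilising transform `Y = arcsin(2 M/N − 1)` on the design
matrix `[1, adult, offspring, adult×offspring]` (treatment coding, warm
= 1). Under the beta-binomial model the delta-method variance of `Y` for
a pooled window is `(N + phi·Q) / N²` up to the constant the transform
absorbs, where `Q = Σ n(n−1)` over the window; the weights are its
reciprocal, `w = N² / (N + phi·Q)`. Samples with an empty window are
dropped at that site; a site is *testable* only if every factorial cell
retains a sample and the design stays full rank.

Wald statistics `beta / se` are referred to a Student-t distribution with
`(samples present − 4)` degrees of freedom rather than a normal: the
weights use an *estimated* dispersion, and with 54 samples the normal
reference is measurably anti-conservative (null rejection at p < 0.05 of
~0.067–0.072 versus the nominal 0.05; the t reference restores
0.049–0.062 across seeds). P-values are BH-adjusted per term
(`scipy.stats.false_discovery_control`).

### Dispersion estimation

Per-site `phi` comes from a method-of-moments fit on the smoothed pooled
counts: the across-sample variance of the pooled proportion is equated to
its beta-binomial expectation and solved for `phi`. Two corrections
matter at this sample size:

- the sample variance is multiplied by `k/(k−1)` (Bessel; without it
  `phi` is biased low by ~4% and the tests anti-conservative), and
- each site estimate is shrunk toward the genome-wide mean with prior
  weight 20 (per-site MoM estimates from ~50 samples are noisy; shrinkage
  stabilises the weights without flattening real variation).

Estimates are clamped to `[1e-4, 0.99]`.

## DMR calling

Within each chromosome and term, significant sites (`fdr <
sig_threshold`; 0.001 on full data) are clustered: a new cluster starts
when the gap to the previous significant site exceeds `merge_dist =
100 bp`. A candidate region spans the first to last significant site of a
cluster; its members are **all tested CpGs inside the span**. Rules then
applied in order: density (≥ `pct_sig = 50%` of members significant),
merging of adjacent regions closer than `merge_dist` when the merged
region still meets the density rule, and minimum size (span ≥ `min_len =
50 bp` and ≥ `min_cpg = 3` member CpGs). Clustering *significant* sites
(rather than segmenting all tested sites by gap) is essential: at
realistic CpG spacing (~50 bp) consecutive tested sites are almost always
closer than `merge_dist`, and segmenting all sites would chain entire
chromosomes into one segment.

`area_stat` is the sum of member Wald statistics; `dmr_mean_diff` is the
difference of pooled proportions (`Σm/Σn`) between groups over the
region.

## Jackknife verification

One subset per full-sib family, containing every sample *not* in that
family (14 subsets for the default design). Each subset re-runs the
entire pipeline — coverage filter (threshold recomputed from the subset's
own size), smoothing, dispersion, tests, DMR calling — at a relaxed
significance of 0.05 on adjusted values, since each subset has less
power and the question is persistence, not rediscovery. A full-data DMR
is **verified** iff in *every* subset some same-term subset DMR covers ≥
80% of its length (single best candidate by default;
`union_overlap=True` pools fragments). Family-driven artefacts fail in
the subset dropping the driving family; planted simulations show ≥90% of
family-confounded calls failing while true-signal sensitivity stays at
1.0. Subsets are skipped when the full data yields no DMRs at all.

## Redundancy analysis

Within each parental-temperature group, the complete-case sample×site
proportion matrix is column-centred and regressed on treatment-coded
predictors (family, offspring temperature); constrained axes are the
principal components of the fitted values (eigenvalues of the
fitted-value covariance, divisor n−1) and `adj R² = 1 − (1−R²)(n−1)/(n−1−m)`
(Ezekiel).

Terms are tested sequentially (Type I) by permutation of reduced-model
residuals: for term *k*, residuals `E` of the model holding terms
`1..k−1` are permuted and the pseudo-F

```
F = (SS_term / df_term) / (SS_resid / df_resid)
```

recomputed; `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` with 999
permutations by default. Because both projectors annihilate the
reduced-model fit, each permuted statistic depends on `E` only through
its row/column-permuted Gram matrix `G = E Eᵀ`, so a permutation costs
O(n²) regardless of the number of sites.

Two documented properties:

- **The second sequential term is conservative at small n.** With ~27
  samples per group, the offspring-temperature term's empirical size at
  nominal 0.05 is ~0.005–0.02. An independent oracle (R `vegan`,
  `anova.cca(..., by="terms")`) shows the same behaviour on identical
  data (~0.03), so this is a property of sequential residual-permutation
  tests at these sizes, not an implementation artefact. The first
  (family) term calibrates at 0.06–0.08. Conservatism only costs power;
  it never inflates false positives.
- **Saturated fits**: when the model explains Y exactly, the residual SS
  is floating-point cancellation noise (possibly negative); any
  `SS_resid ≤ 1e-12 · trace(G)` is treated as an infinite pseudo-F, for
  observed and permuted statistics alike.

## Annotation

DMR–transcript overlap uses half-open interval intersection after
extending transcripts by each flank (0 and 5000 bp by default; touching
endpoints do not overlap). Term enrichment is a one-sided hypergeometric
tail test per term against the background gene universe, BH-corrected,
significant at FDR < 0.05.

## The synthetic study generator

`make_design` builds the breeding design: per parental-temperature group,
one full 2×2 cross (4 families) and one partial cross missing a family
(3 families), two offspring per family split across offspring
temperatures where possible, singleton cells alternating — 14 families,
54 offspring, 27 per parental group. `simulate_methylome` then draws:

- CpG positions: multinomial gaps (≥2 bp) over `n_chrom = 2` chromosomes
  of `chrom_len = 250 kb`, `n_cpg = 10,000` total (~50 bp mean spacing —
  a realistic density for a weakly CpG-depleted genome, and necessary
  for 1–2 kb regions to contain ≥3 tested CpGs);
- coverage: gamma-Poisson (negative binomial), mean `target_coverage =
  15`, shape 8 — overdispersed like real WGBS libraries;
- baseline methylation: bimodal Beta mixture (30% hypo / 10%
  intermediate / 60% hyper), matching the U-shaped genome-wide
  distribution of vertebrate methylomes;
- effects on the logit scale: planted DMRs (`dmr_delta = 0.3` expressed
  as the proportion difference at a 0.5 baseline, halved symmetrically
  around the baseline so the pooled group difference ≈ delta),
  iid per-(site, family) normal family effects (`family_sd`, default
  0.3; 0 gives a pure beta-binomial null), and family-confounded
  regions where a single driver family is shifted by
  `confound_logit_offset = 2.0`;
- counts: `q ~ Beta(p·c, (1−p)·c)` with `c = (1−phi)/phi`,
  `m ~ Binomial(n, q)` — exactly the beta-binomial the tests assume, with
  `dispersion_phi = 0.1`.

`plant_ct_snps` plants family-correlated artifactual C/T sites (a SNP
segregates within the families carrying it) and returns the 1 bp BED used
for masking. Ground truth (`SimTruth`) carries every planted interval.

**Scope and limits.** The generator validates the statistics, not the
biology: no sequence context, no strand, no correlated methylation beyond
what smoothing assumes, family effects iid across sites (no linkage), and
SNPs only at CpG sites. Problem sizes (10⁴ CpGs, 500 kb) are the
package's own choice: large enough for stable calibration estimates and
dozens of non-overlapping 1–2 kb regions, small enough that the full test
suite runs in minutes on one CPU.

## Default parameters at a glance

| Parameter | Default | Why |
|---|---|---|
| coverage bounds | 5–80 in ≥80% of samples | unstable ratios below, repeats above |
| smoothing window | 500 bp | scale of local methylation correlation |
| full / subset significance | FDR 0.001 / 0.05 | strict discovery, lenient persistence |
| DMR rules | ≥50 bp, ≥3 CpGs, ≥50% sig, merge 100 bp | exclude single-CpG and sparse artefacts |
| verification overlap | ≥80% in all subsets | high bar against family-driven calls |
| RDA permutations | 999 | p resolution 0.001 |
| transcript flanks | 0 and 5000 bp | direct overlap and promoter-range proximity |
| dispersion prior weight | 20 | stabilises per-site MoM at ~50 samples |
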