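# Methods

This note documents the statistical procedures implemented in
`omniscreen`, the synthetic-data model used to exercise them, the
parameter choices that matter, and what the tests do and do not establish
about real data.

## Tissue-specificity screen

For gene *g* with mean expression xᵢ in tissue i (arithmetic mean over the
tissue's sampling sites, computed on the linear TPM scale), the
specificity index is

τ = Σᵢ (1 − xᵢ/maxⱼ xⱼ) / (n − 1).

τ is computed after site aggregation and after removing genes whose
maximal tissue mean is strictly below the detectability floor
(`min_max_tpm`, default 10 TPM; a gene exactly at the floor is kept).
No log transform is applied by default: the index is scale-invariant per
gene either way, but log-transforming compresses the normalized profile
x̂ and changes ranks; the linear scale is the simpler convention and the
one the screen's thresholds were calibrated against. An all-zero profile
leaves x̂ undefined and is an error rather than a silent zero.

Selection takes genes whose arg-max tissue equals the target (first tissue
wins ties) with τ strictly greater than `tau_min` (default 0.9), sorted by
τ descending (ties: max expression descending, then gene id) and truncated
to `top_n` (default 100). Fluid-detectable candidates are the intersection
with the fluid-proteome table, ranked by fluorescence intensity from high
to low; when several proteome rows map to one gene the maximum intensity
is kept, since detectability is an existence claim.

## Rank-based group comparisons

All group contrasts (diagnosis, grade, anatomic region, recurrence) are
independent samples, so the "Wilcoxon test" is the two-sample rank-sum
(Mann–Whitney) test, two-sided unless a direction is part of the
hypothesis (as in the marker-like criteria). With ≤ 8 observations per
side, or ≤ 10 pooled, the p-value comes from exhaustive enumeration of all
C(n_a+n_b, n_a) label assignments on the pooled (average) ranks — valid
under ties because the ranks are fixed by the pooled data; larger samples
use the tie-corrected normal approximation with continuity correction.
Significance codes: ns (p > 0.05), * (p < 0.05), ** (p < 0.01),
*** (p < 0.001). A p-value exactly at a threshold belongs to neither open
interval; it is assigned the weaker category. No multiple-testing
correction is applied to figure-style pairwise panels; the enrichment
stage applies Benjamini–Hochberg across gene sets.

## Survival analysis

Kaplan–Meier estimation and the k-group log-rank chi-square test
(df = k − 1) are delegated to `lifelines`; subjects censored at an event
time are counted at risk at that time. `survival_at` evaluates the step
function right-continuously; queries beyond the last observed time return
the last value and are flagged as extrapolation. Expression splits use
median (default) or tertile cutpoints with ties assigned to the lower
group; the split scheme is always an explicit parameter because real
cutpoints vary between studies. Methylation status is beta > 0.3
(strictly; the boundary is unmethylated) — the cutoff is configurable and
every report names it. Two markers' calls combine into four joint strata
in the fixed order unmeth+unmeth, unmeth+meth, meth+unmeth, meth+meth;
samples lacking a call for either marker are dropped with a logged count.
No Cox regression or covariate adjustment is provided: the workflow is
deliberately nonparametric.

## Marker-like screen

Each criterion is a one-sided rank-sum test at p < α (default 0.05):

1. promoter beta higher in glioma (LGG ∪ GBM pooled) than normal, passing
   if **any** annotated promoter probe passes; the smallest-p probe is the
   gene's "best probe";
2. promoter beta higher in LGG than GBM (same any-probe rule);
3. expression higher in LGG than GBM;
4. expression lower in glioma (pooled) than normal.

`passes_all` is the conjunction; genes without a promoter probe fail
criteria 1–2 with an explicit reason and every screened gene appears once
in the audit table. Passing genes are partitioned by the Spearman
correlation between expression and best-probe beta across tumor samples
(LGG ∪ GBM): negative/positive when p < α with that sign, otherwise
"uncorrelated" — an explicit third category, since a signed split need not
be exhaustive. Note that the four criteria themselves induce a positive
between-group component in the pooled tumor correlation (both methylation
and expression are higher in LGG), so negative-coupling genes must carry a
strong within-group signal to be recovered; the synthetic generator's
coupling strength (below) was chosen with that in mind. Enrichment is the
one-sided hypergeometric tail P(X ≥ overlap) against a user-supplied
universe (default: all screened genes), BH-adjusted across sets.

## Cross-omics associations

Spearman correlations (average ranks on ties) between a gene's expression
and its CNV axis — numeric segment means when present, else the ordinal
coding loss = −1, neutral = 0, gain = +1 — within loss/gain strata and
pooled, and between expression and each promoter probe's beta. Stratified
and pooled runs use the same pair-exclusion rule (a pair contributes iff
both values are present); fewer than 3 pairs, or a constant margin,
yields no correlation with a reason instead of a number. The
`simulate_simpson_cnv` construction demonstrates why the stratified view
is the informative one: positive within-stratum coupling can coexist with
a reversed pooled correlation when a stratum-level confound (e.g.
methylation silencing concentrated in one stratum) shifts the means.

## Synthetic-cohort model

The generators emulate the ordering/sign/correlation structure the
analysis assumes, not the marginal distributions of any real cohort.

**Tissue panel.** Background genes draw i.i.d. log-normal expression with
mean `base_mean` = 20 TPM and log-scale σ = 0.5 in every sampling site;
planted genes have mean `specificity_fold` × `base_mean` (default fold 50,
giving an expected τ ≈ 1 − 1/50 ≈ 0.98) in the target tissue only. Noise
is parameterized so the expected value equals the mean
(exp(σz − σ²/2) factor).

**Glioma cohort** (defaults: 30 normal / 40 LGG / 40 GBM samples, 200
genes, 20 marker-like of which 8 negative- and 8 positive-coupled).
Expression is log-normal around group means; marker-like genes start at
100 TPM in normal tissue with log2 fold changes −1.5 (LGG vs normal) and
−0.75 (GBM vs LGG), i.e. roughly 2- and 1.7-fold drops against a log-scale
σ of 0.5 — about a 1-σ standardized LGG/GBM separation, large enough for
one-sided rank-sum power near 1 at n = 40/40 while keeping the
between-group contribution to the pooled correlation moderate. Beta values
are Beta-distributed with precision ν = 50 (sd ≈ 0.07 near the middle of
the unit interval) around planted means 0.20 (normal), 0.45 (GBM), 0.52
(LGG) on the first of each gene's two promoter probes; the second promoter
probe and the non-promoter probe stay at 0.30 in all groups, exercising
the at-least-one-probe rule. The within-tumor methylation–expression
coupling is a Gaussian copula with latent correlation ±0.75; combined with
the between-group component this yields pooled tumor Spearman correlations
around −0.4 / +0.75 for negative/positive planted genes, recoverable at
n = 80 tumors. Null genes are identically distributed in all groups.
Inconsistent plantings (shifts that cannot satisfy all four criteria) are
rejected before any sampling. Setting `expr_sigma = 0` and
`beta_precision = inf` gives the noise-free, effect-only cohort used to
check exact recovery.

**Survival.** Event times are exponential with per-stratum hazards
(cohort default 0.02/month for LGG, 0.08/month for GBM; two-marker cohort
0.12/0.08/0.05/0.03 across the four strata, chosen so the 20-month
survival spans ≈ 0.09–0.55). A `censor_rate` fraction of subjects receives
an independent uniform(0, 60 months) administrative censoring time; with
rate 0 every subject is an event, keeping the KM estimand simple.

**CNV.** Tumor samples draw status loss/neutral/gain with probabilities
0.2/0.6/0.2 and Gaussian segment means centered at −0.5/0/+0.5; normals
are neutral. No expression–CNV coupling is planted in the cohort (the
Simpson construction covers that case separately).

What passing tests show — and do not. Recovery of planted structure
demonstrates that each procedure detects the pattern it targets at the
documented effect sizes and sample sizes, with controlled false positives
on exchangeable nulls. It does not validate effect-size estimates on real
cohorts (no attempt is made to match real marginals, batch structure,
probe cross-reactivity, or non-exponential hazards), and the generator's
defaults are study conditions of this artifact, not estimates of any
published cohort.

## Numerical and design choices

- Strict inequalities throughout where a published rule states them:
  removal below 10 TPM (value exactly 10 kept), τ > 0.9, beta > 0.3 for
  "methylated", p strictly below each significance threshold.
- Ties: average ranks everywhere; arg-max ties resolve to the first tissue
  in input order; τ-score ties in selection break by max expression then
  gene id; split-point ties go to the lower expression group.
- Matrices are genes (probes) × samples internally; files with samples in
  rows are transposed explicitly, never guessed. Identifiers are opaque
  strings; no symbol mapping.
- Expression must be complete and non-negative; beta values may be missing
  (excluded pairwise downstream) but never outside [0, 1].
- All randomness flows from `numpy.random.default_rng(seed)`; the pipeline
  derives per-stage seeds from the master seed in a fixed order, and all
  writers fix float formatting, so a config + seed reproduces every output
  byte for byte. The run manifest records version, seed, thresholds and
  per-file SHA-256.
- Problem sizes in the analysis and test suite (e.g. 2,000-replicate null
  calibration at n = 100/group, 20-seed screen recovery on 200-gene
  cohorts, 200-replicate stratum-ordering checks) were chosen as the
  smallest sizes at which the binomial noise of the estimated rates is
  comfortably inside the asserted bands.

## Known limitations

- The exact rank-sum path enumerates combinations and is exponential in
  group size; it is restricted to ≤ 8 per side (≤ 10 pooled) by design.
- The log-rank test uses the chi-square approximation; no permutation
  variant is offered, so very small strata rely on asymptotics.
- The screen treats genes independently: no shrinkage across genes and no
  multiplicity correction over the 4-way criterion family (the audit table
  retains all p-values so a caller can apply one).
- The enrichment stage assumes the universe is the correct background;
  with a biased universe the hypergeometric p-values inherit that bias.
- Normalization of raw arrays/sequencing (RMA, TPM quantification, beta
  computation from IDAT) is upstream of this package; matrices are taken
  as given and only their unit label is recorded.
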