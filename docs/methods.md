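# Methods

This document records the statistical models, rule tables, parameter
defaults, and numerical choices implemented in `hybridvigor`, along with
known limitations. Claims about statistical behavior (calibration, power,
recovery) refer to properties asserted by the test suite
(`tests/`), which exercises them on seeded synthetic data.

## 1. Phenotypes and residual feed intake (`phenotypes`)

Raw per-bird records carry daily feed consumption (DFC, g/d), start/end
body weight (g), total egg mass over the test period (g), and the test
length in days. Derived traits:

- **MBW** metabolic body weight = ((bw_start + bw_end)/2)^0.75, grams.
- **BWG** daily body-weight gain = (bw_end − bw_start)/test_days.
- **DEM** daily egg mass = total egg mass / test_days.
- **FCR** = DFC / DEM; hens with zero egg mass get FCR = NaN and a
  `no_eggs` flag.
- **RFI** = residual of the OLS regression DFC ~ 1 + MBW + BWG + DEM,
  fitted by `statsmodels`. Zero-egg hens are excluded from the fit by
  default and keep RFI = NaN. Residuals of an intercept model sum to
  zero over the fitted set; the fit requires ≥ 5 complete rows and a
  full-rank design.

`adjusted_group_means` reports per-group mean ± SE (equivalent to OLS on
group indicators). No covariate adjustment beyond the RFI regression is
implemented; published "adjusted means" can be supplied directly to the
heterosis table in bypass mode.

## 2. Mid-parent heterosis (`heterosis`)

For a cross mean F̄ and parental line means P̄f, P̄m:

    MP = (P̄f + P̄m) / 2
    H  = (F̄ − MP) / MP          (× 100 for percent)

H is undefined when MP = 0 (raised as `UndefinedHeterosisError`; in
table mode the single cell is flagged instead of failing the run). When
MP is near zero — as for RFI, which is a residual centred near zero — H
in percent is numerically huge and not interpretable as an effect size.

Significance uses the transformed t statistic

    t = H / [ 2·SD_F / ((P̄f + P̄m)·√n) ],   df = n − 1,

where SD_F is the sample SD of the n cross individuals. Algebraically
t = (F̄ − MP)·√n / SD_F, the ordinary one-sample t of the cross values
against MP; the test suite verifies this identity to 1e-10 on random
inputs and verifies ~5 % type-I error at the null. Note the test treats
the parental means as known constants (no parental sampling variance),
which matches the transformed-t definition but understates uncertainty
when parental groups are small.

## 3. Expression normalization (`expression`)

- **FPKM** = count / ((length/1e3) · (library/1e6)); library sizes
  default to column sums.
- **Expressed filters**: `any_sample` (FPKM > 0 anywhere) and
  `tissue_30pct` (FPKM > 0 in strictly more than 30 % of the chosen
  samples).
- **PCA**: counts are normalized by median-of-ratios size factors,
  transformed as log2(x + 1), and passed to scikit-learn PCA;
  per-group 95 % confidence ellipses use the chi-square(0.95, 2)
  quantile on the per-group covariance. This log transform is a simpler
  substitute for published variance-stabilizing transforms and affects
  only visualization coordinates, not any statistical call.

## 4. Differential expression (`diffexpr`)

A self-contained negative-binomial Wald engine:

- **Size factors**: median-of-ratios against the geometric-mean
  reference over features positive in every sample; falls back to
  relative column sums (with a warning) when no such feature exists.
- **Dispersion**: per-feature method-of-moments pooled across groups on
  normalized counts, floored at 1e-8 (the Poisson limit). No shrinkage
  across features.
- **Model**: per-group log-mean fitted by Newton iterations on the NB
  log-likelihood with known dispersion; expected Fisher information
  I_g = Σ_i μ_i/(1 + α μ_i). Groups that are all zero for a feature get
  a pseudo-mean of half a normalized count; fully zero features are
  flagged (`all_zero`, p = 1).
- **Contrasts**: any dict {group: weight}. On the default log scale the
  estimate is Σ c_g β_g (log2 reported) with variance Σ c_g²/I_g. With
  `scale="mean"` the statistic is Σ c_g·exp(β_g) with delta-method
  variance Σ c_g² μ_g² / I_g — used for the mid-parent contrast
  {F: +1, P1: −½, P2: −½}, because on the log scale that contrast tests
  the *geometric* parental mean while additivity is defined on the
  *arithmetic* mean. The test suite shows the mean-scale version does
  not reject crosses planted exactly at the arithmetic mid-parent,
  while the log-scale version does.
- **Significance**: two-sided normal p on the Wald z; BH-adjusted
  (step-up, verified against `statsmodels.multipletests`); a call
  requires padj < α (default 0.05) and |log2fc| > 1.2 (the threshold is
  a literal log2-scale cutoff). The fold-change gate applies only to
  the log-scale statistic.

Deliberately omitted relative to mature DE packages: log-fold-change
shrinkage, dispersion shrinkage/trend, outlier (Cook's) filtering, and
GLM offsets beyond size factors. Exact agreement with any published
package is not claimed; the engine's null calibration (~5 % raw p < 0.05)
and power (≥ 90 % at planted |log2fc| = 3, dispersion 0.05, n = 8/group)
are asserted in the acceptance tests.

## 5. Inheritance classification (`inheritance`)

Each feature gets four contrast outcomes in {up, down, ns}: parent 1 vs
parent 2, cross vs each parent, and cross vs mid-parent (mean scale).
The decision cascade, applied in order:

1. cross above both parents → **OVERDOMINANT**;
   below both → **UNDERDOMINANT**;
2. parents differ and the cross matches the high parent while exceeding
   the low parent → **DOMINANT_HIGH**; matches the low parent while
   below the high parent → **DOMINANT_LOW**;
3. parents differ and cross vs mid-parent is ns → **ADDITIVE**;
4. all four ns → **CONSERVED**;
5. anything else → **AMBIGUOUS** (no bin).

Twelve numbered bins refine the categories by which parent is higher
and whether the parents differ: additive {4, 10}, dominant-high {3, 11},
dominant-low {5, 9}, overdominant {1, 2, 12}, underdominant {6, 7, 8}.
Relabeling the parents mirrors the bins (1↔12, 3↔11, 4↔10, 5↔9, 6↔8)
and leaves categories invariant; the tests verify this over all 81
outcome combinations against an independently written rule table.
"Non-additive" = dominant + over-/underdominant. Note ADDITIVE is an
accept-the-null call (cross vs mid-parent ns), so low power inflates it.

## 6. lncRNA candidates and targets (`targets`)

Candidate filter, applied in a fixed stage order with per-stage
attrition counts: length ≥ 200 nt, max FPKM ≥ 1, read coverage ≥ 2,
≥ 2 exons, assembly class code in {i, u, x}, coding potential (kept if
it matches a known lncRNA, or if *all* coding predictors are negative),
and no protein-domain (Pfam) hit.

- **cis**: gene within `window` (default 100 000 bp, inclusive — an
  edge-to-edge gap of exactly 100 000 qualifies) of the lncRNA on the
  same chromosome. Coordinates are 1-based inclusive; the gap between
  touching or overlapping intervals is 0. Verified exactly against a
  brute-force oracle and the generator's truth list.
- **trans**: Pearson |r| ≥ 0.95 (inclusive) between lncRNA and gene
  expression over shared samples (≥ 3 required); zero-variance profiles
  are skipped with a warning. No p-value or multiplicity control is
  applied to trans calls — the threshold is the published-style cutoff.

## 7. Co-expression networks (`network`)

Signed weighted-network analysis:

- **Adjacency** a_ij = ((1 + cor(x_i, x_j))/2)^β, zero diagonal.
- **Soft threshold**: for each power, the scale-free fit is the signed
  R² of log10 p(k) vs log10 k over equal-count degree bins; β is the
  smallest power reaching fit ≥ 0.8, else the argmax power (with a
  warning). Homogeneous-degree networks (pure modules, no background)
  may never reach 0.8 — the fallback handles this.
- **TOM** similarity = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
  ℓ_ij = Σ_u a_iu a_uj; verified to 1e-12 against an O(n³) brute force.
- **Modules**: average-linkage hierarchical clustering of 1 − TOM with
  a static height cut chosen to maximize the number of clusters of at
  least `min_size` (ties → lower cut, which yields purer clusters);
  unassigned features are then rescued into a module when their
  |eigengene correlation| exceeds 0.7; modules whose eigengenes are
  closer than the merge cut (1 − r < 0.25) are merged iteratively,
  closest pair first, and relabeled by size.
- **Eigengene**: first right singular vector of the z-scored member
  matrix, sign-oriented to correlate positively with mean expression,
  unit norm.
- **Module–trait**: Pearson r of eigengenes with traits, p from the
  t distribution with n − 2 df; gene significance (GS) = |cor(gene,
  trait)|, module membership (MM) = |cor(gene, eigengene)|; hub genes
  require GS > 0.7 and MM > 0.7 (strict).
- **Preservation**: density (mean within-module adjacency in the test
  network) and connectivity (correlation of intramodular connectivity
  vectors between networks); permutation null shuffles module labels;
  Zsummary = median of the two Z scores. Interpretation: > 10 strong,
  2–10 weak-to-moderate, < 2 none. The acceptance tests assert
  self-comparison Zsummary > 10 (200 permutations) and |Zsummary| < 2
  on label-destroyed data.

Differences from the reference WGCNA implementation: static rather than
dynamic tree cut (plus the kME rescue step), no block-wise processing,
and merge on eigengene dissimilarity only.

## 8. Enrichment (`enrichment`)

Upper-tail hypergeometric test: p = P(X ≥ k) for k query hits in a set
with K members of an N-feature universe and an n-feature query,
computed as `scipy.stats.hypergeom.sf(k−1, N, K, n)`. Sets with K = 0
or k = 0 are reported but excluded from the BH family (p = padj = NA);
enriched means padj < α. The query must be a subset of the universe.

## 9. Synthetic data (`simulate`)

All generators take one seed, use a single `numpy` Generator stream,
and are byte-reproducible. Defaults are fixed at the study conditions
and are not tuned per test.

- **Phenotypes**: per-group trait means default to the published-scale
  adjusted means (DFC/DEM) with plausible BW/BWG values; per-bird SDs
  (DFC 14, DEM 9, BW 150, BWG 2) give SEs near 1 g/d at n = 200. DFC is
  built as mean + β·(X − E[X]) + N(0, noise_sd), so planted group means
  and the RFI regression structure are exact in expectation.
- **Counts**: NB draws (Poisson when dispersion < 1e-8) at group means
  realizing a planted inheritance bin per feature: log2 offsets of
  `effect_log2fc` (default 3) around a baseline of 500; additive bins
  put the cross at the *arithmetic* parental mid.
- **Co-expression**: 3 modules × 60 genes with loadings 0.7–0.9 on
  latent factors, gene noise SD 0.5, plus 60 pure-noise background
  genes (heterogeneous degrees are needed for the scale-free criterion
  to be attainable); the trait is module 1's factor plus noise.
- **Annotation**: two 5 Mb chromosomes, 50 genes, 20 lncRNA, half
  planted within the cis window of a random gene; the truth list is
  computed by brute force over all pairs, so incidental proximity
  counts.

## 10. Numerical choices

- Dispersion floor 1e-8; all-zero groups fitted at half a normalized
  count; Newton iterations on the log-mean with step halving.
- BH implemented as the standard step-up with cumulative minima;
  verified against `statsmodels`.
- Height grid for the static tree cut: midpoints of consecutive unique
  linkage heights plus just below the top merge.
- Pearson p values use the exact t transformation rather than normal
  approximations.
- All tabular I/O is plain TSV/CSV/GTF/GMT text; GTF coordinates stay
  1-based inclusive end-to-end.

## 11. Limitations

- The heterosis t treats parental means as constants; no
  covariate-adjusted (model-based) group means are computed.
- The DE engine has no shrinkage or outlier handling and is not a
  drop-in replacement for published packages on real data.
- ADDITIVE/CONSERVED calls accept a null hypothesis and therefore grow
  with noise; the AMBIGUOUS bin absorbs incoherent contrast patterns
  rather than forcing a call.
- Static tree cut can split one planted module across cuts in
  unfavorable seeds; the kME rescue mitigates but does not eliminate
  this (mean adjusted Rand index ≥ 0.9 over seeds is the asserted
  property, not per-seed perfection).
- Trans target calling is a bare correlation threshold with no
  multiplicity control.
- The pipeline's synthetic stages are desk-scale (hundreds of features)
  and not benchmarked for genome-scale inputs.
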