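# Methods

## Generative model

Each simulated dataset is a gene × sample matrix of Poisson reads driven by
latent multivariate-Gaussian log-concentrations.  For sample `s` in class
`c(s)`:

    x_s ~ N( μ(c(s)), σ² R ),      count(g, s) ~ Poisson( a · d_s · e^{x_s[g]} )

* **Mean structure.** All features share one baseline latent mean
  (`baseline_log_mean`, default 0 on the natural-log scale; the absolute
  count scale comes entirely from depth calibration, so this value only
  matters relative to itself).  Globally DE features add `lfc_de · ln 2`
  to the class-2 mean; heterogeneous markers add the same shift only in
  `ceil(n_subgroups/2)` randomly chosen class-1 subgroups (recorded in the
  ground truth).  The default effect is `lfc_de = 1` (fold change 2): at 50
  samples per class it is reliably detectable at σ = 0.4 and substantially
  harder at σ = 0.7, which is exactly the easy/difficult contrast the two
  presets encode.  All DE shifts are positive by default, so simulated
  datasets show the overexpression-skewed volcano geometry typical of
  mean-shift simulators.
* **Covariance.** `R` is block compound symmetry: within each designed
  block of `block_size` features every off-diagonal equals `block_rho`;
  everything else is independent.  Compound symmetry of size k is positive
  definite iff ρ ∈ (−1/(k−1), 1), enforced at validation.  Only the k × k
  blocks are ever factorized (Cholesky), so the full n × n matrix is never
  materialized and 10,000-feature simulations stay cheap.
* **Feature layout.** Deterministic: DE markers occupy the first feature
  indices, heterogeneous markers the next, correlation blocks the
  following ones.  The layout carries no statistical content (features are
  exchangeable under the model) and is fully recorded in `GroundTruth`.
* **Depth calibration.** The rate scale `a` is found by fixed-point
  iteration `a ← a · target/empirical_mean` on a pilot simulation of the
  same dimensions (the pilot latent matrix is drawn once; only the Poisson
  stage repeats), stopping within 1% of the target and capped at 20
  iterations, after which a diagnostic error reports the last pilot mean.
  Since the Poisson mean is linear in the rate, the loop converges in 2–3
  iterations.  The default target of 300 reads per feature puts the
  presets on the typical depth scale of a polyA bulk RNA-seq cohort.
* **Marginal behaviour.** Counts are Poisson-log-normal:
  Var = μ + (e^{σ²}−1)μ², i.e. method-of-moments NB dispersion
  φ ≈ e^{σ²}−1 (≈ 0.17 at σ = 0.4, ≈ 0.63 at σ = 0.7) and BCV ≈ σ.
  On the rank scale, a latent Pearson correlation ρ maps to a Spearman
  correlation of roughly (6/π)·asin(ρ/2) ≈ 0.385 for ρ = 0.4, slightly
  attenuated further by Poisson noise — so recovered within-block Spearman
  values near 0.37–0.39 at large n are the model's own design value, not a
  deficiency.
* **Randomness.** One root seed; every randomized stage (latent draw,
  depth jitter, Poisson sampling, subgroup choice, feature subsampling,
  off-block pair sampling, balanced subsetting) draws from a named
  substream derived from it, so stages are independently reproducible and
  identical (config, seed) pairs give byte-identical outputs.

What the generator deliberately does **not** emulate: a realistic spread of
baseline expression across genes (all features share one latent mean, so
the mean–dispersion trend of simulated data is flat rather than the
decreasing curve of real cohorts — itself a useful diagnostic contrast),
gene-length or GC effects, library-composition artefacts, zero inflation,
and single-cell sparsity.  Passing tests on simulated data therefore
demonstrate correctness of the machinery and calibration under the model's
assumptions, not fidelity to any real tissue.

## Data preparation

Mirrors standard two-class cohort preparation: drop features whose median
count is 0 (midpoint convention for even sample counts), subset to a
balanced number of samples per class without replacement (seeded), and clip
counts above a ceiling (default 10⁷) to the ceiling, reporting how many
entries were clipped.  The filter and the subset commute only
approximately; the CLI applies whichever order the user invokes and logs it.

## Metric battery

* **Q-Q concordance.** Values are compared on log2(count+1) (count ranges
  span orders of magnitude; raw mode available).  Samples pair up by
  library-size rank — robust to arbitrary column order and exact under
  self-comparison — and each pair contributes 99 matched type-7 quantiles,
  an OLS line (closed form; a constant quantile axis is flagged degenerate
  rather than fit), the maximum absolute quantile gap, and the exact
  two-sample KS statistic of the underlying vectors.  Dataset-level
  numbers are means over pairs.
* **Dispersion and mean–variance.** Per-gene moments use size-factor
  normalized counts with the unbiased variance; φ = max(0, (v−m)/m²) under
  Var = μ + φμ²; the trend is a running median over 20 equal-occupancy
  bins of log mean, linearly interpolated between bin medians with
  constant extrapolation.  Equal-occupancy bins keep medians stable where
  means are sparse.  Two datasets are compared as the median of
  |log((t_b+δ)/(t_a+δ))| over a 50-point shared log-mean grid, δ = 10⁻³ —
  symmetric, scale-robust, and exactly 0 for identical trends.  The same
  construction applies to the mean–variance relationship.
* **Correlation structure.** Up to 25 non-constant features are selected
  (seeded); Spearman correlations (average ranks, then Pearson) are
  computed for all pairs on log2(count+1) within each class separately and
  pooled, so between-class mean shifts cannot masquerade as feature–feature
  correlation; a raw pooled mode reproduces the naive behaviour.  Two
  datasets are compared by the two-sample KS distance between their pooled
  correlation distributions; the same selection substream is used on both
  sides so self-comparison is exactly 0.  Block recovery contrasts the mean
  within-block Spearman against a seeded sample of off-block pairs (10×
  the number of within-block pairs).
* **Differential expression.** Median-of-ratios size factors (positive-
  subset fallback when no feature is everywhere positive); a delta-method
  NB Wald test on log2 of pseudocounted (ε = 0.5) normalized class means
  with se = sqrt(Σ_k (m_k + φ m_k²)/(n_k (m_k+ε)²))/ln 2; two-sided normal
  p-values; Benjamini–Hochberg adjustment (statsmodels).  The dispersion
  feeding the test is the method-of-moments estimate of the *residual*
  variance around the two class means (within-class pooled), floored by
  its running-median trend: estimating dispersion from raw pooled moments
  would let a true expression difference inflate the noise term of the very
  gene carrying it and visibly costs power at small sample sizes, while the
  residual-based estimate keeps the type-I error at the nominal rate.
  Design-blind dispersion estimates can still be supplied explicitly.
  Volcano classes use p < 0.05 (strict) and |lfc| > 1; p = 0 is mapped to
  a finite −log10 ceiling.  This procedure is intentionally simple and
  analytically checkable; it is not a re-implementation of any published
  DE package, and absolute discovery counts are expected to differ from
  such packages at the margin (the comparison framework only consumes
  counts at a common threshold on both sides).
* **Separability.** PCA on per-feature-centered log2-CPM (prior 0.5), no
  scaling, no gene preselection by default (a top-k option exists);
  component signs fixed by making the largest-magnitude loading positive.
  The separability scalar is the mean silhouette of the class labels on
  (PC1, PC2) — a 2-D visual judgement turned into a rankable number.
* **Ranking.** Each criterion ranks generators by ascending distance
  (DEG criterion by |deg_count − deg_count_input|), ties broken
  lexicographically by name.  Criteria are deliberately *not* aggregated
  into one score: different generators win different criteria, and the
  per-criterion table is the result.

## Problem sizes and defaults used in checks

The automated checks run the full 10,000 × 100 presets where the design
values live (dimensions, 500 DE flags, 1%-calibrated mean of 300, DEG
envelope), a 50-feature × 2000-sample simulation for block-correlation
recovery (small feature count, since only the 5 block features enter the
statistic), 5,000 × 100 null NB data for Wald calibration, and the
500 × 20 scaled presets elsewhere — the scaled presets keep every
statistical parameter (σ, ρ, DE fraction, target mean) identical to the
full ones and shrink only the dimensions.  One known consequence: with 10
samples per class the default effect size is underpowered for BH discovery
(a minority of the 25 designed DE features reach q ≤ 0.05), so
count-matches-design assertions belong to the full-scale presets while the
scaled ones check FDR control and nonzero sensitivity.

## Known limitations

* Single shared baseline mean ⇒ no realistic mean–dispersion curve.
* The Wald test uses a normal reference; at very small n (< ~5 per class)
  it will be anticonservative.
* Spearman on counts attenuates the designed latent correlation (see
  above); the battery reports what is recoverable from counts, by design.
* KS statistics on discrete counts are conservative in small samples.
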