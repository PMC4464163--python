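# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the synthetic data the tests rely on, and the
numerical decisions that matter for reproducibility.

## Differential expression: the correlated two-sample t

Each gene is tested for an induced-vs-uninduced difference within one
genotype. Replicates are paired by replicate index (biological replicate
*i* of the treated group against replicate *i* of the control group), and
the statistic is

t = (X̄₁ − X̄₂) / √((σ̂²₁ + σ̂²₂ − 2 γ̂ σ̂₁ σ̂₂) / n),  df = n − 1,

with sample variances (n−1 denominator) and γ̂ the sample Pearson
correlation between the two replicate vectors. The identity
s²_d = σ̂²₁ + σ̂²₂ − 2γ̂σ̂₁σ̂₂ for the per-pair differences makes this
*exactly* the paired t-test, which the test suite verifies to 1e-10 on
random data. Consequences worth knowing:

- Type-I error is exact under paired Gaussian noise for any within-pair
  correlation, including ρ = 0; the calibration tests confirm a rejection
  rate inside [0.040, 0.060] at α = 0.05 over 20,000 null genes.
- Positive within-pair correlation (shared biological or batch signal
  between a treated/control pair) *increases* power relative to the
  independent two-sample t; this is the reason the correlation enters the
  statistic at all.
- With n = 3 the statistic has only 2 degrees of freedom; P-values are
  heavy-tailed and power is modest. This matches the intended study scale
  and is not worked around (no variance moderation — see Limitations).

Estimator conventions the statistic leaves open are fixed as: sample
variance with n−1; γ̂ as the plain sample Pearson coefficient; γ̂ := 0 when
either replicate vector has zero variance (the correlation is undefined
there, and 0 reduces the statistic to the independent form). Degenerate
genes — zero variance of differences with unequal means — would give
t = ±∞; they are flagged, assigned p = 0 with a runtime warning, and
reported rather than silently propagating infinities. Zero variance with
equal means gives t = 0, p = 1.

The DEG call is raw two-sided P strictly below `deg_alpha` (default 0.05).
An FDR column (Benjamini–Hochberg step-up, via
`statsmodels.stats.multitest.multipletests`) is always reported, and
`threshold_on="fdr"` switches the call to it; raw P is the default because
that is the conventional screen at this study scale. The output metadata
records `fdr_method: benjamini-hochberg`.

## Network projection

The regulatory network is a set of directed TF→target pairs plus a tested
gene universe. "Pairs involving at least one DEG" is read as *either
endpoint* (TF or target) being a DEG — the reading that retains the most
evidence — with `target_only` available as configuration, since either
reading is defensible and the choice measurably changes retained-pair
counts. The filter is monotone in the DEG set (property-tested).

Two distinct objects matter downstream and are deliberately not conflated:

- the **active subnetwork** (pairs touching a DEG) decides *which TFs are
  tested* and is what one would export to a graph viewer;
- each tested TF's **full regulon** — all its targets in the whole network,
  intersected with the universe — supplies the contingency table. Using the
  DEG-filtered pairs as the regulon would empty the b cell (non-DEG
  targets) and spuriously inflate every TF's significance.

The enrichment universe is the set of genes detected in the expression
matrix, not the union of network genes; regulons are intersected with it,
and TFs whose intersected regulon is empty are reported but not ranked.
TFs need not themselves be DEGs, nor lie in the universe, to be ranked.

## TF enrichment: exact Fisher at extreme tails

For targets T, DEGs D and universe U, the cells are a = |T∩D|, b = |T\D|,
c = |D\T|, d = |U\(T∪D)|. Conditioning on both margins makes the a-cell
hypergeometric. The two-sided P-value follows the minimum-likelihood
convention: the sum of point probabilities of all support values whose pmf
does not exceed the observed one, with a relative tie slack of 1e-7 so
exactly-tied tables on the far side are included despite floating-point
representation. One-sided `greater`/`less` options are retained for
sensitivity analysis; both include the observed point's mass, so their sum
is always ≥ 1.

Numerics: log point-probabilities come from a cached log-factorial table
(equivalent to log-gamma); included terms are exponentiated and accumulated
with compensated summation (`math.fsum`) smallest-first. Each term is
representable down to ~1e-308, so two-sided P-values at the 1e-17 scale —
and far beyond — are computed to near machine relative accuracy. The test
suite verifies every 2×2 table with n ≤ 60 against full enumeration in
exact rational arithmetic (observed worst relative error ~1e-13, asserted
≤ 1e-9) and cross-checks random and regulon-scale tables against an
independent library implementation.

Depletion is first-class: a regulon with fewer DEG targets than the
background rate earns a small two-sided P and `direction: depleted`
(the sign of a·d − b·c). Ranking is by ascending P with lexicographic
tie-break on TF id, so output order is total and deterministic.
Significance is raw P < `tf_alpha` (default 0.01) with **no across-TF
correction** — the screen this pipeline mirrors works on raw P — but a
BH-adjusted column is emitted for users who prefer it.

## Two-way clustering

Gene rows of the DEG submatrix are standardized to mean 0, variance 1
(constant rows map to zeros), then genes and samples are clustered
independently by agglomerative linkage (`scipy.cluster.hierarchy`) on
euclidean or correlation distance; defaults are euclidean + complete,
matching common R heatmap defaults. Standardization is applied before both
axes' clustering, consistent with what a row-scaled heatmap displays. The
linkage is deterministic given input order; scipy's tie handling is
adopted as the documented tie rule. Dendrograms expose the merge table,
the leaf order, and a `cut(k)` helper used by the structure checks.

## Synthetic data

The generator emulates a replicated two-genotype, two-treatment microarray
study on the log2 scale. Per gene: baseline ~ N(8, 1.5); each
treated/control replicate pair receives bivariate Gaussian noise with
standard deviation `noise_sd` and correlation `pair_correlation`; planted
DEGs add ±`effect_size` (random sign) to the induced group. The knockout
genotype's planted set is a superset of the wild-type set, scaled by
`ko_deg_multiplier`. The network draws each TF's regulon size uniformly
from `targets_per_tf`; active TFs sample targets with planted-DEG odds
`active_odds_ratio` times background (weight-proportional sampling without
replacement); TF ids are themselves genes, so TFs can be DEGs and
self-regulation can occur. Active regulons are enriched against the shared
wild-type planted core, so active TFs carry signal in both contrasts.

Defaults and rationale (units: log2 intensity unless noted):

| parameter | default | why |
|---|---|---|
| n_genes | 10,000 | typical detected-gene count on a mouse 430 array |
| n_replicates | 3 | the standard minimal replicated design |
| deg_fraction | 0.15 | wild-type planted load; with the default effect this yields a ~15–16% *called* DEG rate, the scale reported for such studies |
| effect_size | 1.5 | calibrated so realized power at n = 3 makes the called rate match the planted scale above; ~3-fold change |
| noise_sd | 0.5 | common per-measurement SD for array log2 intensities |
| pair_correlation | 0.5 | moderate shared replicate signal; makes the correlated t distinguishable from the independent t |
| ko_deg_multiplier | 2.0 | knockout strata in sensitized models roughly double the DEG load |
| n_tfs / targets_per_tf | 1,000 / (5, 50) | ≈ 26 targets per TF, the density of public TF→target resources |
| n_active_tfs / active_odds_ratio | 50 / 5 | a small truly-active subset with clearly elevated but not degenerate enrichment |

All stages derive independent generators from one `SeedSequence`, so runs
are bit-reproducible per seed and stages can be regenerated in isolation.

What the generator does *not* emulate: probe-level effects and
summarization, intensity-dependent variance, batch structure, correlated
DEG blocks (co-regulation), or scale-free network topology. Passing tests
therefore demonstrate correctness of the statistics and plumbing under a
clean Gaussian model, not robustness to real-array artifacts.

A note on one limiting case: because the t statistic is scale-invariant,
shrinking `noise_sd` does **not** silence null genes as long as the noise
is representable — their P-values stay uniform. The "vanishing noise calls
exactly the planted set" behaviour is realized only when the noise
underflows against the baseline (differences exactly zero), and that is how
the corresponding test exercises it.

## Pipeline and determinism

`run_pipeline` executes, per contrast (induced-vs-uninduced within
genotype, derived from the design or set in the config): DEG calling →
pair filtering → TF ranking → clustering, then compares the first two
contrasts' top-k TF sets. Any stage failure aborts with the stage name.
All tables are written as TSV with P-values in scientific notation; the
manifest records versions, seed, thresholds and every headline count
(DEGs, retained pairs, TFs tested/significant, top-k overlap), and the
tests audit manifest counts against the emitted tables. Reruns with the
same config are byte-identical.

Problem sizes in the test suite and acceptance script (10,000–20,000 genes
per calibration, 20 seeds for FDR, three replicate studies for recovery,
the exhaustive Fisher grid at n ≤ 60) were chosen as the smallest sizes at
which the binomial/Monte-Carlo tolerances quoted in the tests are
comfortably non-flaky.

## Known limitations

- No variance moderation (limma-style shrinkage): at n = 3 the per-gene
  variance estimate is noisy and a moderated t would be more powerful; the
  plain correlated t is implemented because it is the method under study.
- The FDR method is fixed to Benjamini–Hochberg; no Storey/π₀ estimation.
- No mid-P or conditional-MLE odds ratios for the Fisher test.
- The network is treated as given truth; no edge confidence weights.
- Clustering offers no bootstrap support or optimal leaf ordering.
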