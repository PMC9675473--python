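# Methods

This note records the statistical procedures implemented in
`nephromac`, the parameter defaults and why they were chosen, what the
synthetic generators do and do not emulate, the numerical choices, and
the known limitations. Every empirical number quoted here is computed by
the test suite or by `scripts/acceptance.py`.

## 1. Quality control and normalization (`preprocess`)

Per-cell metrics: total counts, number of detected genes (nonzero
entries), and mitochondrial fraction (counts on genes whose id starts
with `mt-`, case-insensitive, divided by total; defined as 0 for an
empty cell). Filters, applied cells-first then genes:

| parameter | default | rationale |
|---|---|---|
| `min_genes` | 200 | standard droplet-QC floor; removes empty/low-content barcodes |
| `max_genes` | 2500 | upper bound against multiplets and ambient-heavy cells |
| `max_mito_frac` | 0.05 (strict `<`) | stressed/dying-cell ceiling for kidney tissue |
| `min_cells_per_gene` | 3 | drops genes with no usable variation |

Normalization rescales each cell to the **median pre-filter total**
`m`: counts in cell `j` are multiplied by `m / t_j`. The invariant —
every post-normalization total equals `m` — is exact up to floating
point (max relative deviation ~1e-15 over random matrices).

Highly variable genes follow the classic mean/dispersion recipe on
log1p-transformed normalized data: genes are placed into 20
equal-frequency bins of mean expression, the variance/mean dispersion
is z-scored within each bin, and a gene is selected when
`0.0125 < mean < 3` and `z ≥ 0.5`. Bin assignment is
`(rank · n_bins) // n_genes` on a stable sort of the means, which makes
the equal-frequency rule deterministic under ties.

## 2. Doublet-cluster flagging

Input: per-cell doublet scores (any upstream scoring method) and
cluster labels, with ≥ 3 clusters required. Per-cluster medians `m_c`
are converted to robust z-scores

    z_c = (m_c − median(m)) / (1.4826 · MAD(m)),

upper-tail p-values are taken from a Student *t* reference, BH-adjusted
across clusters, and a cluster is flagged iff `p_adj < 0.1` (strict).

**Degrees of freedom.** The naive choice `df = n_clusters − 1` treats
the MAD-based scale as if it were a sample standard deviation. It is
not: the MAD's asymptotic efficiency relative to the sd is ≈ 0.37, so
the scale estimate from ~10 cluster medians carries roughly 37% of the
information, and the naive *t* reference is far too light-tailed. The
default is therefore `df = 0.37 · (n_clusters − 1)`, derived from that
efficiency constant rather than tuned. Measured on 500 null replicates
of 10 exchangeable clusters, the fraction with any false flag is 0.052
(vs 0.182 with the naive df); detection of a planted doublet cluster
(Beta(8,4) scores against Beta(2,20) singlets) is 100/100. The naive
*t* and a normal reference remain available via `tail="t-naive"` /
`tail="normal"`.

## 3. Recovery-AUC gene-set scoring (`scoring`)

Genes are ranked per cell by descending expression, ties broken by
ascending gene index (a stable sort on negated values), so the ranking
is fully deterministic. With `top_frac = 0.05` (the conventional AUCell
window) the threshold is `T = ceil(top_frac · n_genes)`. For a set with
`s` genes at ranks `r_1 … r_s`, the un-normalized score is
`Σ_{r_i ≤ T} (T − r_i + 1)` — the area under the step recovery curve —
and the reported score divides by the maximally packed area
`Σ_{i=1..min(s,T)} (T − i + 1)`, giving exactly 1 when the set occupies
the top ranks and 0 when no set gene enters the window. Because only
ranks enter, the score is invariant to any strictly monotone transform
of expression (property-tested with hypothesis). Agreement with an
independent brute-force step-curve walk is exact to ≤ 1e-12 over random
cells.

Group-level summaries are the per-cluster mean score matrix and its
min-max scaled companion (min → 0, max → 1 along the chosen axis; a
constant slice maps to 0, "no contrast to display").

## 4. Rank-sum markers and group tests

`rank_sum_test` is two-sided Wilcoxon/Mann-Whitney via
`scipy.stats.mannwhitneyu`. `method="auto"` uses the exact distribution
when both groups have ≤ 8 observations and there are no ties, else the
tie-corrected normal approximation with continuity correction. The
exact path agrees with full enumeration of all `C(n1+n2, n1)` group
assignments to ≤ 1e-9.

`wilcoxon_markers` tests each cluster (≥ 2 cells) against all remaining
cells per gene with the asymptotic path, BH-adjusts within the
contrast, and reports the top genes among those with `p_adj < 0.05`
(strict) and a positive shift. Under a global null the probability of
reporting any marker is ≤ 0.05 by construction of BH (measured 0.04
over 200 simulations).

`pairwise_group_test` compares all unordered group pairs and
Bonferroni-adjusts with multiplier `C(g, 2)` (capped at 1); groups with
< 2 observations are skipped with a warning.

## 5. Cross-dataset similarity (`similarity`)

A glmnet-style ridge (`alpha = 0`) logistic regression ensemble:

- The reference (two classes; the lexicographically larger label is the
  positive class) is standardized per gene; zero-variance genes are
  dropped.
- Penalty path: `λ_max = max_j |x_j'(y − ȳ)| / n / 1e-3` (the ridge
  adaptation of glmnet's entry point), then **50** log-spaced values
  down to `λ_max · 1e-4`. 50 points (not glmnet's default 100) resolve
  the deviance curve to well within one cross-validation standard error
  at half the fitting cost; this is a deliberate numerical choice.
- Each of `n_iterations = 50` iterations draws a fresh 10-fold
  stratified partition (seeded `seed + iteration`), computes the
  cross-validated binomial deviance along the path with a warm-started
  lbfgs solver (`C = 1/(n·λ)`, `tol = 1e-6`), and applies the **1-SE
  rule**: the largest penalty whose mean deviance is within one
  standard error of the minimum. The model is then refit on all cells
  at that penalty.
- Query scoring standardizes the query per gene with its own statistics
  by default (`standardize_with="train"` reuses reference moments);
  ensemble genes absent from the query contribute 0 after
  standardization. The score is the mean predicted positive-class
  probability over iterations.

Measured under study-like conditions (two clusters of 200 cells, 100
genes, 10 markers each at 8-fold change): matched-minus-mismatched mean
score 0.94, accuracy 1.0 at a 0.5 threshold; degenerate scores under
label swap mirror to `1 − s`.

## 6. Spatial colocalization (`spatial`)

Neighborhoods are k-nearest-neighbor sets on array coordinates
(Euclidean distance, stable sort, ties broken by spot index, focal spot
first), with `k = 7` — the focal spot plus its 6 immediate lattice
neighbors, the natural first shell of a hex/grid array. For each
neighborhood the Pearson correlation (Spearman optional) of the two
channels is computed; a constant channel slice yields a missing value.
Each spot's raw score is the mean over all neighborhoods containing it
(overlapping averaging smooths single-neighborhood noise), and
**positive-only retention** sets scores ≤ 0 to missing: the display
contract is "where do the two signatures co-occur", so anti- and
un-correlated neighborhoods are blanked rather than shown.

The per-spot statistic agrees with an independent brute-force
enumeration (all-pairs distance sort, textbook Pearson, explicit
averaging) to ≤ 1e-12 on random grids. With a correlation of 0.8
planted in the cortex of a 20×20 grid, cortex-interior spots (those
whose whole neighborhood stays in cortex) show a median score ≈ 0.74.

**Sparsity is quoted over all spots.** Under the null the per-spot
averaged correlation is symmetric about zero, so positive-only
retention keeps roughly half the *outside-cortex* spots no matter what;
the meaningful sparsity statement is that retained outside-cortex spots
are a small fraction (≈ 0.22–0.33 across generator seeds) of the
**whole map**. The fraction is seed-dependent near 0.3 because boundary
spots whose neighborhoods overlap the correlated cortex leak positive
scores.

Glomerular spots are those whose podocyte-signature channel strictly
exceeds its 0.95 quantile (an absolute `threshold` alternative is
provided; exactly one rule must be set). Composition over a spot set
renormalizes the listed subset channels per spot to sum to 1, drops
all-zero spots (count reported), and averages; the result sums to 1.

## 7. Synthetic generators (`synthetic`)

`simulate_cells` draws negative-binomial counts (mean `μ`, variance
`μ + μ²/θ`, defaults `μ = 2`, `θ = 2` — overdispersion typical of
droplet data) over clusters with planted marker genes whose mean is
multiplied by `marker_fold_change = 8`. Doublets are the rounded mean
of two random singlet profiles from different clusters; doublet scores
are Beta(8,4) vs Beta(2,20) for singlets (clearly separated but
overlapping, as real scrublet-like scores are). Mitochondrial fractions
are planted by sizing a multinomial split between an `mt-` block and
nuclear genes. Two "strains" (control/disease) mix 50/50 in every
cluster except the last, which is 90% disease — emulating a
disease-enriched population. Optional outlier cells violate each QC
rule on purpose.

`simulate_spatial` lays a spot grid with concentric kidney-like
regions (pelvis at normalized center distance < 0.4, medulla < 0.75,
cortex rim, 5% of cortex spots as glomeruli), draws channel pairs from
a bivariate normal (mean 0.5, sd 0.15, correlation ρ inside the target
region, 0 outside) clamped to [0, 1], gives glomeruli Beta(20,4)
podocyte signal vs Beta(2,20) elsewhere, and plants composition
channels around a target mixture.

**What the generators do not emulate:** ambient RNA, batch/chemistry
effects, library-size gradients, spatial autocorrelation within a
region beyond the planted channel correlation, realistic gene-gene
correlation structure, zero inflation beyond the NB, spot swapping or
tissue-detection errors. They exist to give the pipeline quantities
with known ground truth, not to fool a practitioner.

All generators are deterministic functions of their `seed`
(`numpy.random.default_rng`); byte-identical reruns are tested.

## 8. Numerical choices

- Matrices are CSR `genes × cells`; scaling uses sparse diagonal
  multiplication, never densification of large matrices.
- All rankings and neighbor searches use stable sorts with explicit
  index tie-breaks, making every statistic deterministic.
- Spatial I/O writes floats with `%.17g` (round-trip exact for
  doubles); missing values round-trip as empty fields.
- Derived RNG seeds are reduced mod 2³¹ − 1 to stay in the valid range.

## 9. Limitations

- The doublet-flagging reference is an approximation: the constant
  0.37 is the MAD's *asymptotic* efficiency, applied at small
  `n_clusters`. It is conservative and well calibrated in the tested
  regimes (~10 clusters) but is not an exact small-sample distribution.
- The similarity module is strictly two-class; one-vs-rest multiclass
  composition is left to the caller.
- Neighborhood correlation on `k = 7` points is noisy per neighborhood;
  overlapping averaging mitigates but does not remove this, and the
  positive-only retention threshold at 0 is a display convention, not a
  significance test.
- The 0.95-quantile glomerulus rule assumes glomeruli are rare; on a
  tissue where they are common an absolute threshold is more
  appropriate.
- Exact rank-sum enumeration is limited to ≤ 8 observations per group
  and tie-free data; beyond that the asymptotic approximation is used.
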