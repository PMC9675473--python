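# nephromac

Statistical toolkit for kidney-macrophage single-cell and spatial
transcriptomics: quality control and doublet-cluster flagging for
scRNA-seq, gene-set activity scoring, rank-sum marker statistics,
cross-dataset population similarity by penalized logistic regression,
and spatial neighborhood colocalization on Visium-style spot lattices —
together with seeded synthetic generators that plant every quantity the
pipeline is supposed to recover.

## Scientific problem

In lupus nephritis, infiltrating monocyte-derived macrophages and
resident macrophage populations redistribute across kidney anatomy
(cortex, glomeruli, medulla, pelvis), and their transcriptional programs
colocalize with immune-complex and injury signatures in space. Analyzing
this requires a chain of statistical steps, each of which is easy to get
subtly wrong:

- **QC and normalization.** Cells are kept when they detect 200–2,500
  genes and carry < 5% mitochondrial counts; genes must appear in ≥ 3
  cells. Every cell is rescaled so its total equals the median pre-filter
  total: for totals `t_j` and median `m`, counts are multiplied by
  `m / t_j`, so post-normalization totals are exactly `m`.
- **Doublet-cluster flagging.** Per-cluster median doublet scores `m_c`
  are reduced to robust z-scores
  `z_c = (m_c − median(m)) / (1.4826 · MAD(m))`; an upper-tail p-value
  from a Student *t* reference with effective degrees of freedom
  `0.37 · (n_clusters − 1)` (the MAD's asymptotic efficiency) is
  BH-adjusted across clusters, and a cluster is flagged iff
  `p_adj < 0.1`.
- **Gene-set scoring (recovery AUC).** Genes are ranked per cell
  (ties broken by gene index); with threshold `T = ceil(0.05 · n_genes)`,
  the score is the area under the set-recovery step curve within the top
  `T` ranks, normalized by the maximally packed area — invariant to any
  monotone transform of expression.
- **Markers and group tests.** Cluster-vs-rest Wilcoxon rank-sum tests
  (exact enumeration for small tie-free samples, tie- and
  continuity-corrected normal approximation otherwise), BH within each
  contrast; pairwise group comparisons are Bonferroni-adjusted by the
  number of unordered pairs `C(g, 2)`.
- **Similarity (ridge logistic ensemble).** A two-class reference is
  standardized per gene and fit along a 50-point log-spaced ridge
  penalty path; each of 50 iterations reshuffles a 10-fold stratified
  partition, picks the largest penalty within one standard error of the
  minimum cross-validated binomial deviance (the 1-SE rule), and refits
  on all cells. Query cells are scored by the mean predicted
  positive-class probability across iterations.
- **Spatial colocalization.** Each spot's neighborhood is its k = 7
  nearest spots (itself included) on array coordinates; the Pearson
  correlation of two signature channels is computed per neighborhood,
  each spot receives the mean over all neighborhoods containing it, and
  non-positive scores are set to missing (positive-only retention).
  Glomerular spots are those strictly above the 0.95 quantile of a
  podocyte signature; macrophage-subset composition there is the mean of
  per-spot renormalized proportions.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on
synthetic data with planted truth and write their tables under
`results/`:

```bash
python analysis/01_simulate.py        # seeded datasets
python analysis/02_qc_doublets.py     # QC, doublet flags, HVG
python analysis/03_score_genesets.py  # AUCell, enrichment, markers
python analysis/04_similarity.py      # ridge-logistic ensemble (~80 s)
python analysis/05_spatial_coloc.py   # colocalization, glomeruli
```

Output at the default seed (0):

```
cells: 525 cells x 500 genes, 25 doublets in cluster 'DBL', 289 disease-strain cells
spatial: 400 spots — cortex=208, medulla=120, pelvis=52, glomerulus=20
doublet flagging: ['DBL'] of 6 clusters flagged
QC: kept 501/525 cells and 500/500 genes; 117 highly variable
enrichment: 100% of signatures peak in their own cluster
markers: 25 cluster-top genes reported, 100% are planted markers of their cluster
pairwise: C0_signature differs in 8/15 cluster pairs (Bonferroni < 0.05)
similarity: matched mean 0.970, mismatched mean 0.028, gap 0.942, accuracy at 0.5 = 1.000
penalties: median selected lambda 0.03393 over 50 iterations
colocalization: cortex median 0.736 over 226 retained cortex spots; 105/400 retained spots lie outside the cortex
glomeruli: 20 spots selected (precision vs truth 100%, 0 dropped as all-zero); composition trmac_sig=0.546, momac_sig=0.298, dc_sig=0.156
```

The planted doublet cluster is the only one flagged; every cluster
signature peaks in its own cluster; all de-novo markers are planted
markers; the similarity ensemble separates matched from mismatched query
cells by 0.94; the cortex — where a correlation of 0.8 was planted —
shows a median colocalization score of 0.74 while positive-only
retention keeps the map sparse elsewhere; and the recovered glomerular
composition (0.546/0.298/0.156) matches the planted mixture
(0.55/0.30/0.15).

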