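"""Gene-set recovery-AUC scoring and rank-based group statistics.

The per-cell enrichment score follows the AUCell construction: genes are
ranked within each cell by decreasing expression, a recovery curve counts
how many gene-set members appear within the top ``top_frac`` of the
ranking, and the score is the area under that step curve normalized by the
maximum achievable area for the set. The score depends only on ranks, so it
is invariant to monotone transforms of a cell's expression vector.

Group comparisons use the Wilcoxon rank-sum test with BH correction within
each cluster-vs-rest contrast (marker genes) or Bonferroni across unordered
group pairs (score comparisons between conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, GeneSet, ValidationError


@dataclass
class AUCellParams:
    top_frac: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.top_frac <= 1:
            raise ValidationError("top_frac must be in (0, 1]")


# ---------------------------------------------------------------------------
# ranking and recovery AUC
# ---------------------------------------------------------------------------

def rank_genes_per_cell(matrix: ExpressionMatrix) -> np.ndarray:
    """Genes x cells array of ranks, 1 = highest expression in that cell.

    Ties are broken by ascending gene index (deterministic), i.e. a stable
    sort on decreasing expression.
    """
    X = matrix.dense()
    # stable argsort on -x preserves gene order within ties
    order = np.argsort(-X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(X.shape[1])[None, :]
    ranks[order, cols] = np.arange(1, X.shape[0] + 1)[:, None]
    return ranks


def _recovery_auc(set_ranks: np.ndarray, threshold: int, set_size: int) -> float:
    """Normalized area under the step recovery curve for one cell.

    ``set_ranks`` are the ranks (1-based) of the set genes in this cell. The
    curve runs over rank positions 1..threshold; at position x it has height
    = number of set genes with rank <= x. The area is the sum of heights
    over the threshold positions, normalized by the maximum achievable area
    (all min(set_size, threshold) set genes packed at the top).
    """
    hits = np.sort(set_ranks[set_ranks <= threshold])
    if hits.size == 0:
        return 0.0
    # area = sum_{x=1..T} (#hits <= x) = sum over hits of (T - rank + 1)
    area = float(np.sum(threshold - hits + 1))
    k = min(set_size, threshold)
    max_area = float(np.sum(threshold - np.arange(1, k + 1) + 1))
    return area / max_area


def aucell_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    params: AUCellParams | None = None,
    *,
    normalize_by_max: bool = True,
    ranks: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell recovery-AUC enrichment score in [0, 1] for one gene set.

    ``normalize_by_max=False`` divides by the full rectangle
    ``set_size x threshold`` instead of the maximal packed area (the
    alternative normalization); the default gives a fully recovered small
    set a score of 1. Precomputed ``ranks`` (from :func:`rank_genes_per_cell`)
    can be passed to amortize the sort across many sets.
    """
    params = params or AUCellParams()
    gidx = matrix.gene_index()
    members = [gidx[g] for g in gene_set.genes if g in gidx]
    if not members:
        raise ValidationError(
            f"no gene of set {gene_set.name!r} present in the matrix"
        )
    if ranks is None:
        ranks = rank_genes_per_cell(matrix)
    threshold = int(np.ceil(params.top_frac * matrix.n_genes))
    set_ranks = ranks[members, :]  # members x cells
    in_top = set_ranks <= threshold
    area = np.where(in_top, threshold - set_ranks + 1, 0).sum(axis=0).astype(float)
    set_size = len(members)
    if normalize_by_max:
        k = min(set_size, threshold)
        max_area = float(np.sum(threshold - np.arange(1, k + 1) + 1))
    else:
        max_area = float(set_size * threshold)
    return area / max_area


def score_gene_sets(
    matrix: ExpressionMatrix,
    gene_sets: list[GeneSet],
    params: AUCellParams | None = None,
) -> pd.DataFrame:
    """Cells x sets table of recovery-AUC scores (shared ranking pass)."""
    ranks = rank_genes_per_cell(matrix)
    cols = {
        gs.name: aucell_score(matrix, gs, params, ranks=ranks) for gs in gene_sets
    }
    return pd.DataFrame(cols, index=matrix.cell_ids)


# ---------------------------------------------------------------------------
# group-mean enrichment with 0-1 scaling
# ---------------------------------------------------------------------------

def group_mean_enrichment(
    scores: pd.DataFrame,
    groups: np.ndarray,
    scale_axis: str = "rows",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean per-group score table plus its min-max scaled companion.

    Rows are group labels, columns gene sets. Scaling maps min -> 0 and
    max -> 1 along the requested axis; a constant row/column maps to 0
    (no contrast to display). Empty groups yield NaN rows with a warning.

    Returns ``(means, scaled)``.
    """
    if scale_axis not in ("rows", "cols"):
        raise ValidationError("scale_axis must be 'rows' or 'cols'")
    groups = np.asarray(groups)
    if len(groups) != len(scores):
        raise ValidationError("one group label per cell required")
    means = scores.groupby(groups, observed=True).mean()
    if means.isna().any().any():
        warnings.warn("some groups have no cells; NaN rows emitted", stacklevel=2)
    axis = 1 if scale_axis == "rows" else 0
    mn = means.min(axis=axis)
    mx = means.max(axis=axis)
    rng = mx - mn
    scaled = means.sub(mn, axis=1 - axis).div(rng.where(rng > 0, np.inf), axis=1 - axis)
    return means, scaled


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------

def rank_sum_test(
    x: np.ndarray, y: np.ndarray, *, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``method`` is ``"exact"`` (full permutation distribution, valid for
    small tie-free samples), ``"asymptotic"`` (normal approximation with tie
    correction and continuity correction), or ``"auto"`` (exact when both
    samples have <= 8 observations and no ties, else asymptotic).

    Returns ``(U statistic of x, p value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "auto":
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_markers(
    matrix: ExpressionMatrix,
    clusters: np.ndarray,
    n_top: int = 5,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cluster-vs-rest marker genes by the rank-sum test with BH correction.

    Every cluster with >= 2 cells is compared against all remaining cells,
    gene by gene, with the asymptotic tie-corrected test; p-values are
    BH-adjusted across genes within each contrast. The returned table keeps,
    per cluster, the ``n_top`` genes with the smallest p among genes with
    adjusted p < ``alpha`` and positive enrichment (higher mean rank) in
    the cluster.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != matrix.n_cells:
        raise ValidationError("one cluster label per cell required")
    labels = [lab for lab in pd.unique(clusters)]
    sizes = {lab: int((clusters == lab).sum()) for lab in labels}
    usable = [lab for lab in labels if sizes[lab] >= 2]
    for lab in labels:
        if sizes[lab] < 2:
            warnings.warn(f"cluster {lab!r} has < 2 cells; skipped", stacklevel=2)
    if len(usable) < 2 and len(labels) < 2:
        raise ValidationError("need at least 2 clusters")

    X = matrix.dense()
    n1 = {lab: (clusters == lab) for lab in usable}
    rows = []
    for lab in usable:
        mask = n1[lab]
        a, b = X[:, mask], X[:, ~mask]
        na, nb = a.shape[1], b.shape[1]
        # vectorized tie-corrected normal approximation across genes
        allx = np.hstack([a, b])
        ranks = stats.rankdata(allx, axis=1)
        ra = ranks[:, :na].sum(axis=1)
        u = ra - na * (na + 1) / 2
        mean_u = na * nb / 2
        n = na + nb
        tie_term = np.zeros(X.shape[0])
        for g in range(X.shape[0]):
            _, counts = np.unique(allx[g], return_counts=True)
            tie_term[g] = np.sum(counts**3 - counts)
        var_u = na * nb / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u)
        z = np.where(var_u > 0, z, 0.0)
        p = 2 * stats.norm.sf(np.abs(z))
        p = np.clip(p, 0.0, 1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        enriched = u > mean_u  # mean rank in cluster above the rest
        for g in range(X.shape[0]):
            rows.append(
                {
                    "cluster": str(lab),
                    "gene": matrix.gene_ids[g],
                    "enriched": bool(enriched[g]),
                    "u_stat": float(u[g]),
                    "p": float(p[g]),
                    "p_adj_bh": float(p_adj[g]),
                }
            )
    full = pd.DataFrame(rows)
    sig = full[(full["p_adj_bh"] < alpha) & full["enriched"]]
    top = (
        sig.sort_values(["cluster", "p", "gene"], kind="stable")
        .groupby("cluster", sort=False)
        .head(n_top)
        .reset_index(drop=True)
    )
    top.attrs["all_tests"] = full
    return top


def pairwise_group_test(
    scores: np.ndarray,
    groups: np.ndarray,
    *,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """All unordered group pairs compared by the rank-sum test.

    The Bonferroni multiplier is the number of tested pairs; adjusted
    p-values are capped at 1. Groups with fewer than 2 observations are
    skipped with a warning (their pairs are not counted in the multiplier).
    """
    if correction != "bonferroni":
        raise ValidationError("only bonferroni correction is supported")
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = [lab for lab in pd.unique(groups)]
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    usable = []
    for lab in labels:
        if (groups == lab).sum() < 2:
            warnings.warn(f"group {lab!r} has < 2 observations; skipped", stacklevel=2)
        else:
            usable.append(lab)
    pairs = list(combinations(usable, 2))
    if not pairs:
        raise ValidationError("no testable group pair")
    m = len(pairs)
    rows = []
    for a, b in pairs:
        stat, p = rank_sum_test(scores[groups == a], scores[groups == b])
        rows.append(
            {
                "group_a": str(a),
                "group_b": str(b),
                "u_stat": stat,
                "p": p,
                "p_adj_bonferroni": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)
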