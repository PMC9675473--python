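"""QC metrics, cell/gene filtering, median-target normalization, HVG
selection, and cluster-level doublet flagging.

The QC thresholds follow the standard scRNA-seq workflow for mouse kidney
tissue: cells are kept with 200-2,500 detected genes and mitochondrial
content below 5%; genes are kept when detected in at least 3 surviving
cells. Each cell is then scaled so its total count equals the median of
pre-normalization totals.

Doublet flagging operates on per-cell doublet scores (produced upstream by
a dedicated scorer) aggregated per cluster: clusters whose median score is
a robust outlier (median/MAD z-score, one-sided upper-tail test, BH across
clusters at 0.1) are flagged as likely doublet clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, ValidationError


class EmptyResultError(ValueError):
    """A filter removed everything; silent empty output would hide a bug."""


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

def resolve_mito_genes(
    gene_ids: list[str], selector: str | list[str] = "mt-"
) -> np.ndarray:
    """Boolean mask of mitochondrial genes.

    ``selector`` is either a gene-name prefix (matched case-insensitively,
    the convention for mouse ``mt-`` genes) or an explicit gene-id list
    (matched exactly).
    """
    if isinstance(selector, str):
        pref = selector.lower()
        mask = np.array([g.lower().startswith(pref) for g in gene_ids])
    else:
        chosen = set(selector)
        mask = np.array([g in chosen for g in gene_ids])
    if not mask.any():
        warnings.warn(
            "mitochondrial selector matched no gene; mito_frac set to 0",
            stacklevel=2,
        )
    return mask


def compute_qc(
    matrix: ExpressionMatrix, mito_gene_selector: str | list[str] = "mt-"
) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total counts, mito fraction.

    ``mito_frac`` is the fraction of a cell's counts coming from
    mitochondrial genes, 0 for cells with zero total.
    """
    if matrix.layer != "raw":
        raise ValidationError("QC metrics are defined on raw counts")
    csc = sp.csc_matrix(matrix.values)
    n_genes = np.diff(csc.indptr)  # nonzero entries per cell column
    total = np.asarray(csc.sum(axis=0)).ravel()
    mito_mask = resolve_mito_genes(matrix.gene_ids, mito_gene_selector)
    mito_counts = np.asarray(csc[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "n_genes": n_genes.astype(int),
            "total_counts": total,
            "mito_frac": mito_frac,
        }
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class QCParams:
    min_genes: int = 200
    max_genes: int = 2500
    max_mito_frac: float = 0.05
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if not 0 < self.max_mito_frac <= 1:
            raise ValidationError("max_mito_frac must be in (0, 1]")


def filter_cells_genes(
    matrix: ExpressionMatrix, qc: pd.DataFrame, params: QCParams | None = None
) -> ExpressionMatrix:
    """Apply the cell filter, then the gene filter, preserving order.

    Cells survive iff ``min_genes <= n_genes <= max_genes`` and
    ``mito_frac < max_mito_frac``; genes survive iff detected in at least
    ``min_cells_per_gene`` of the *surviving* cells.
    """
    params = params or QCParams()
    qc = qc.set_index("cell_id").loc[matrix.cell_ids]
    keep_cells = (
        (qc["n_genes"].to_numpy() >= params.min_genes)
        & (qc["n_genes"].to_numpy() <= params.max_genes)
        & (qc["mito_frac"].to_numpy() < params.max_mito_frac)
    )
    if not keep_cells.any():
        raise EmptyResultError("all cells removed by the QC filter")
    sub = sp.csc_matrix(matrix.values)[:, keep_cells]
    detected = np.asarray((sub > 0).sum(axis=1)).ravel()
    keep_genes = detected >= params.min_cells_per_gene
    if not keep_genes.any():
        raise EmptyResultError("all genes removed by the detection filter")
    out = sp.csr_matrix(sub[keep_genes])
    return ExpressionMatrix(
        out,
        [g for g, k in zip(matrix.gene_ids, keep_genes) if k],
        [c for c, k in zip(matrix.cell_ids, keep_cells) if k],
        layer=matrix.layer,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_to_median(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every cell so its total equals the median pre-normalization total.

    Preserves within-cell proportions and the zero pattern exactly.
    """
    if matrix.layer != "raw":
        raise ValidationError("normalization expects the raw layer")
    totals = np.asarray(matrix.values.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValidationError(
            "all-zero cells present; run filter_cells_genes first"
        )
    target = float(np.median(totals))
    scale = target / totals
    out = sp.csr_matrix(matrix.values.astype(float) @ sp.diags(scale))
    return ExpressionMatrix(
        out, list(matrix.gene_ids), list(matrix.cell_ids), layer="normalized"
    )


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

@dataclass
class HVGParams:
    min_mean: float = 0.0125
    max_mean: float = 3.0
    min_disp: float = 0.5
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.min_mean >= self.max_mean:
            raise ValidationError("min_mean must be < max_mean")


def hvg_statistics(matrix: ExpressionMatrix, n_bins: int = 20) -> pd.DataFrame:
    """Per-gene mean and bin-standardized dispersion on log1p values.

    Dispersion is the variance/mean ratio of ``log1p`` expression; genes are
    grouped into ``n_bins`` equal-frequency bins of mean expression and each
    gene's dispersion is z-scored against its bin (the classic
    Seurat-flavoured normalized dispersion).
    """
    X = np.log1p(matrix.dense())
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1) if matrix.n_cells > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_genes = len(mean)
    if n_genes < n_bins:
        warnings.warn("fewer genes than bins; using a single bin", stacklevel=2)
        bins = np.zeros(n_genes, dtype=int)
    else:
        # equal-frequency bins by rank of the mean
        order = np.argsort(mean, kind="stable")
        bins = np.empty(n_genes, dtype=int)
        bins[order] = np.minimum(
            (np.arange(n_genes) * n_bins) // n_genes, n_bins - 1
        )
    disp_norm = np.empty(n_genes)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        disp_norm[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean": mean,
            "dispersion": disp,
            "dispersion_norm": disp_norm,
            "bin": bins,
        }
    )


def select_hvg(matrix: ExpressionMatrix, params: HVGParams | None = None) -> list[str]:
    """Genes passing the mean-expression window and the dispersion cutoff."""
    params = params or HVGParams()
    if matrix.layer != "normalized":
        raise ValidationError("HVG selection expects the normalized layer")
    st = hvg_statistics(matrix, params.n_bins)
    keep = (
        (st["mean"] >= params.min_mean)
        & (st["mean"] <= params.max_mean)
        & (st["dispersion_norm"] >= params.min_disp)
    )
    return st.loc[keep, "gene_id"].tolist()


# ---------------------------------------------------------------------------
# cluster-level doublet flagging
# ---------------------------------------------------------------------------

@dataclass
class DoubletClusterReport:
    cluster: str
    median_score: float
    robust_z: float
    p_value: float
    p_adj_bh: float
    flagged: bool
    degenerate_scale: bool = False


# asymptotic efficiency of the MAD relative to the standard deviation for
# normal data: the MAD-based scale behaves like an sd estimated from about
# 37% as many observations, which sets the effective df of the t reference
MAD_EFFICIENCY = 0.37


def flag_doublet_clusters(
    scores: np.ndarray,
    clusters: np.ndarray,
    *,
    alpha: float = 0.1,
    tail: str = "t",
) -> list[DoubletClusterReport]:
    """Flag clusters whose median doublet score is a robust upper outlier.

    Per cluster the median score is computed; the cluster medians are then
    centred on their own median and scaled by 1.4826 x MAD. The robust z of
    each cluster is converted to a one-sided upper-tail p-value and
    BH-corrected across clusters; a cluster is flagged iff its adjusted p
    is strictly below ``alpha`` (default 0.1).

    The default reference (``tail="t"``) is Student t with
    ``MAD_EFFICIENCY * (n_clusters - 1)`` degrees of freedom: the MAD-based
    scale is far noisier than an sd from the same number of medians, and
    pretending otherwise inflates the false-flag rate well beyond the BH
    level. ``tail="t-naive"`` uses ``n_clusters - 1`` df, ``tail="normal"``
    the normal tail (both more liberal).

    If all cluster medians coincide the scale is zero; nothing is flagged
    and the reports carry ``degenerate_scale=True``.
    """
    scores = np.asarray(scores, dtype=float)
    clusters = np.asarray(clusters)
    if scores.shape != clusters.shape:
        raise ValidationError("scores and clusters must align")
    if np.isnan(scores).any():
        raise ValidationError("every cell needs a doublet score")
    labels = pd.unique(clusters)
    if len(labels) < 3:
        raise ValidationError("need at least 3 clusters for outlier testing")
    medians = np.array([np.median(scores[clusters == lab]) for lab in labels])
    center = np.median(medians)
    mad = np.median(np.abs(medians - center))
    scale = 1.4826 * mad
    degenerate = scale == 0
    if degenerate:
        z = np.zeros_like(medians)
        p = np.ones_like(medians)
    else:
        z = (medians - center) / scale
        if tail == "t":
            p = stats.t.sf(z, df=MAD_EFFICIENCY * (len(labels) - 1))
        elif tail == "t-naive":
            p = stats.t.sf(z, df=len(labels) - 1)
        elif tail == "normal":
            p = stats.norm.sf(z)
        else:
            raise ValidationError(f"unknown tail {tail!r}")
    p_adj = multipletests(p, method="fdr_bh")[1]
    flagged = np.zeros(len(labels), dtype=bool) if degenerate else p_adj < alpha
    return [
        DoubletClusterReport(
            cluster=str(lab),
            median_score=float(m),
            robust_z=float(zi),
            p_value=float(pi),
            p_adj_bh=float(pa),
            flagged=bool(fl),
            degenerate_scale=bool(degenerate),
        )
        for lab, m, zi, pi, pa, fl in zip(labels, medians, z, p, p_adj, flagged)
    ]


def doublet_reports_to_frame(reports: list[DoubletClusterReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def mark_doublet_cells(
    clusters: np.ndarray, reports: list[DoubletClusterReport]
) -> np.ndarray:
    """Boolean per-cell mask: cell belongs to a flagged cluster."""
    flagged = {r.cluster for r in reports if r.flagged}
    return np.array([str(c) in flagged for c in np.asarray(clusters)])
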