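"""Synthetic single-cell and spatial data with planted, recoverable structure.

The generators emulate the statistical features the downstream estimators
assume: negative-binomial counts with cluster-specific marker genes, a
doublet subpopulation with an elevated per-cell doublet score, planted
per-cell mitochondrial fractions, two "strain" batches with a
disease-enriched cluster, and a spot lattice with anatomical regions in
which pairs of score channels are correlated at a planted strength inside
one region and uncorrelated elsewhere.

Everything is driven by a single integer seed; the same config and seed
produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ExpressionMatrix, SpatialDataset, ValidationError


class DegenerateConfigError(ValueError):
    """The configuration cannot produce a usable dataset."""


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------

@dataclass
class OutlierSpec:
    """Cells planted to violate the standard QC bounds.

    ``n_low_genes`` cells express almost nothing, ``n_high_genes`` cells are
    over-complex (every gene detected, inflated totals), ``n_high_mito``
    cells get a mitochondrial fraction above any sane cutoff.
    """

    n_low_genes: int = 0
    n_high_genes: int = 0
    n_high_mito: int = 0
    high_mito_frac: float = 0.5


@dataclass
class CellSimConfig:
    n_clusters: int = 5
    cells_per_cluster: int = 100
    n_genes: int = 500
    n_marker_genes_per_cluster: int = 10
    marker_fold_change: float = 8.0
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    doublet_rate: float = 0.05
    # Beta(a, b) parameters for the per-cell doublet score
    singlet_score_dist: tuple[float, float] = (2.0, 20.0)
    doublet_score_dist: tuple[float, float] = (8.0, 4.0)
    # Beta(a, b) for the planted mitochondrial fraction of ordinary cells
    mito_frac_dist: tuple[float, float] = (2.0, 98.0)
    n_mito_genes: int = 10
    # per-cluster probability that a cell comes from the disease strain;
    # default: balanced everywhere except the last cluster, which is
    # disease-enriched (the structure the study reports for inflamed kidneys)
    strain_mixing: list[float] | None = None
    doublet_cluster: str | None = None
    outlier_cells: OutlierSpec = field(default_factory=OutlierSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if not 0 <= self.doublet_rate <= 1:
            raise ValidationError("doublet_rate must be in [0, 1]")
        if self.marker_fold_change <= 1:
            raise ValidationError("marker_fold_change must be > 1")
        if self.strain_mixing is not None:
            if len(self.strain_mixing) != self.n_clusters:
                raise ValidationError("strain_mixing length != n_clusters")
            if any(not 0 <= p <= 1 for p in self.strain_mixing):
                raise ValidationError("strain_mixing entries must be in [0, 1]")

    def resolved_strain_mixing(self) -> np.ndarray:
        if self.strain_mixing is not None:
            return np.asarray(self.strain_mixing, dtype=float)
        probs = np.full(self.n_clusters, 0.5)
        probs[-1] = 0.9  # disease-enriched cluster
        return probs


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: float, size) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + mu^2 / disp."""
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=size)


def simulate_cells(
    config: CellSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a clustered scRNA-seq count matrix with planted truth.

    Returns ``(matrix, annotations, marker_table)``. ``annotations`` has one
    row per cell with ``cell_id, strain, true_cluster, is_doublet,
    doublet_score, planted_mito_frac``; ``marker_table`` lists the genes
    up-shifted per cluster.

    Counts are negative-binomial per gene; cluster markers have their mean
    multiplied by ``marker_fold_change`` in their own cluster. Doublets are
    the element-wise mean of two random singlet profiles, rounded to integer
    counts, and draw their doublet score from the doublet distribution. The
    mitochondrial fraction is planted by sizing a dedicated ``mt-`` gene
    block against each cell's nuclear total.
    """
    rng = np.random.default_rng(config.seed)
    n_singlets = config.n_clusters * config.cells_per_cluster
    if config.doublet_rate > 0 and n_singlets < 2:
        raise DegenerateConfigError(
            "doublets require at least two singlet profiles to pair"
        )
    n_doublets = int(round(config.doublet_rate * n_singlets))
    if config.doublet_rate >= 1:
        raise DegenerateConfigError("doublet_rate must be < 1")

    n_mito = config.n_mito_genes
    n_nuclear = config.n_genes - n_mito
    if n_nuclear < config.n_clusters * config.n_marker_genes_per_cluster:
        raise DegenerateConfigError("not enough nuclear genes for the marker blocks")
    gene_ids = [f"mt-Gene{i}" for i in range(n_mito)] + [
        f"Gene{i}" for i in range(n_nuclear)
    ]

    # per-gene baseline means (lognormal spread around nb_mean), markers shifted
    base_mean = config.nb_mean * rng.lognormal(0.0, 0.5, size=n_nuclear)
    cluster_means = np.tile(base_mean, (config.n_clusters, 1))
    marker_rows = []
    for c in range(config.n_clusters):
        start = c * config.n_marker_genes_per_cluster
        idx = np.arange(start, start + config.n_marker_genes_per_cluster)
        cluster_means[c, idx] *= config.marker_fold_change
        marker_rows += [
            {"cluster": f"C{c}", "gene": gene_ids[n_mito + i]} for i in idx
        ]
    marker_table = pd.DataFrame(marker_rows)

    # singlet nuclear counts
    clusters = np.repeat(np.arange(config.n_clusters), config.cells_per_cluster)
    nuclear = np.vstack(
        [
            _nb_draw(rng, cluster_means[c], config.nb_dispersion, (1, n_nuclear))
            for c in clusters
        ]
    )

    # doublets: mean of two distinct singlets, rounded
    if n_doublets:
        pairs = np.array(
            [rng.choice(n_singlets, size=2, replace=False) for _ in range(n_doublets)]
        )
        d_nuclear = np.rint((nuclear[pairs[:, 0]] + nuclear[pairs[:, 1]]) / 2).astype(
            nuclear.dtype
        )
        nuclear = np.vstack([nuclear, d_nuclear])
        if config.doublet_cluster is not None:
            d_clusters = np.full(n_doublets, -1)
        else:
            d_clusters = clusters[pairs[:, 0]]
        clusters = np.concatenate([clusters, d_clusters])
    n_cells = nuclear.shape[0]
    is_doublet = np.zeros(n_cells, dtype=bool)
    is_doublet[n_singlets:] = True

    # planted mitochondrial fraction: size the mt- block against the nuclear total
    a_m, b_m = config.mito_frac_dist
    mito_frac = rng.beta(a_m, b_m, size=n_cells)
    out = config.outlier_cells
    n_out = out.n_low_genes + out.n_high_genes + out.n_high_mito
    if n_out > n_singlets:
        raise DegenerateConfigError("more planted outliers than singlet cells")
    out_idx = rng.choice(n_singlets, size=n_out, replace=False) if n_out else np.array([], int)
    low_idx = out_idx[: out.n_low_genes]
    high_idx = out_idx[out.n_low_genes : out.n_low_genes + out.n_high_genes]
    hm_idx = out_idx[out.n_low_genes + out.n_high_genes :]
    mito_frac[hm_idx] = out.high_mito_frac

    nuclear[low_idx] = 0
    if low_idx.size:
        # leave a handful of detected genes so totals stay positive
        keep = rng.choice(n_nuclear, size=5, replace=False)
        nuclear[np.ix_(low_idx, keep)] = 1
    if high_idx.size:
        nuclear[high_idx] += 1  # every gene detected -> n_genes == n_genes_total

    nuclear_tot = nuclear.sum(axis=1)
    mito_tot = np.rint(mito_frac / (1 - mito_frac) * nuclear_tot).astype(int)
    mito = np.zeros((n_cells, n_mito), dtype=nuclear.dtype)
    for i in range(n_cells):
        if mito_tot[i] > 0:
            mito[i] = rng.multinomial(mito_tot[i], np.full(n_mito, 1 / n_mito))

    counts = np.hstack([mito, nuclear])

    # doublet scores and strains
    a_s, b_s = config.singlet_score_dist
    a_d, b_d = config.doublet_score_dist
    score = np.where(
        is_doublet,
        rng.beta(a_d, b_d, size=n_cells),
        rng.beta(a_s, b_s, size=n_cells),
    )
    strain_p = config.resolved_strain_mixing()
    p_disease = np.where(clusters >= 0, strain_p[np.clip(clusters, 0, None)], 0.5)
    strain = np.where(rng.random(n_cells) < p_disease, "disease", "control")

    cluster_labels = np.where(
        clusters >= 0,
        np.char.add("C", clusters.astype(str)),
        config.doublet_cluster or "doublet",
    )
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    ann = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "strain": strain,
            "true_cluster": cluster_labels,
            "is_doublet": is_doublet,
            "doublet_score": score,
            "planted_mito_frac": mito_frac,
        }
    )
    matrix = ExpressionMatrix(
        sp.csr_matrix(counts.T), gene_ids, cell_ids, layer="raw"
    )
    return matrix, ann, marker_table


# ---------------------------------------------------------------------------
# spatial simulation
# ---------------------------------------------------------------------------

REGIONS = ("cortex", "medulla", "pelvis", "glomerulus")


@dataclass
class SpatialSimConfig:
    grid_rows: int = 20
    grid_cols: int = 20
    # (chan_a, chan_b, region, rho): plant correlation rho between the two
    # channels inside the region; outside they are independent
    channel_pairs: list[tuple[str, str, str, float]] = field(
        default_factory=lambda: [("sig_a", "sig_b", "cortex", 0.8)]
    )
    noise_sd: float = 0.15
    region_map: np.ndarray | None = None  # explicit assignment, else default layout
    glomerulus_frac: float = 0.05
    # planted composition of macrophage-subset channels in glomerulus spots
    composition: dict[str, float] | None = None
    composition_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b, region, rho in self.channel_pairs:
            if not -1 <= rho <= 1:
                raise ValidationError(f"planted rho {rho} outside [-1, 1]")
            if region not in REGIONS:
                raise ValidationError(f"unknown region {region!r}")
        if self.composition is not None:
            total = sum(self.composition.values())
            if not np.isclose(total, 1.0):
                raise ValidationError("planted composition must sum to 1")


def default_region_map(
    rows: int, cols: int, glomerulus_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Concentric kidney-like layout: cortex rim, medulla ring, pelvis core.

    Glomeruli are scattered within the cortex at the requested fraction of
    all spots, mirroring their anatomical location.
    """
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    # normalized distance from the grid centre
    d = np.hypot(
        (rr - (rows - 1) / 2) / max(rows / 2, 1),
        (cc - (cols - 1) / 2) / max(cols / 2, 1),
    )
    region = np.where(d < 0.4, "pelvis", np.where(d < 0.75, "medulla", "cortex"))
    region = region.astype(object)
    cortex_idx = np.flatnonzero((region == "cortex").ravel())
    n_glom = int(round(glomerulus_frac * rows * cols))
    if n_glom > cortex_idx.size:
        raise ValidationError("glomerulus fraction exceeds cortex size")
    glom = rng.choice(cortex_idx, size=n_glom, replace=False)
    flat = region.ravel()
    flat[glom] = "glomerulus"
    return flat.reshape(rows, cols).astype(str)


def simulate_spatial(config: SpatialSimConfig) -> SpatialDataset:
    """Simulate a spot lattice with planted within-region channel correlation.

    For each ``(a, b, region, rho)`` pair the two channels are drawn from a
    bivariate normal (mean 0.5, sd ``noise_sd``, correlation ``rho``) inside
    the region and independently outside, then clamped to [0, 1]. The
    ``podocyte`` channel is elevated in glomerulus spots. Truth region labels
    ride along in ``dataset.region``.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_rows, config.grid_cols
    n = rows * cols
    if config.region_map is not None:
        region = np.asarray(config.region_map, dtype=str)
        if region.shape != (rows, cols):
            raise ValidationError("region_map shape != grid shape")
        if not set(np.unique(region)) <= set(REGIONS):
            raise ValidationError("region_map contains unknown regions")
    else:
        region = default_region_map(rows, cols, config.glomerulus_frac, rng)
    region_flat = region.ravel()

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    ds = SpatialDataset(
        spot_ids=[f"spot_{r}_{c}" for r, c in zip(rr.ravel(), cc.ravel())],
        array_row=rr.ravel(),
        array_col=cc.ravel(),
        in_tissue=np.ones(n, dtype=bool),
        region=region_flat,
    )

    channels: dict[str, np.ndarray] = {}
    for a, b, reg, rho in config.channel_pairs:
        in_reg = region_flat == reg
        za = rng.normal(size=n)
        zb_indep = rng.normal(size=n)
        zb = np.where(
            in_reg, rho * za + np.sqrt(1 - rho**2) * zb_indep, zb_indep
        )
        for name, z in ((a, za), (b, zb)):
            vals = np.clip(0.5 + config.noise_sd * z, 0.0, 1.0)
            if name in channels:
                # a channel may appear in several pairs; region draws overwrite
                channels[name] = np.where(in_reg, vals, channels[name])
            else:
                channels[name] = vals
    for name, vals in channels.items():
        ds.add_channel(name, vals, score=True)

    glom = region_flat == "glomerulus"
    podo = np.where(glom, rng.beta(20, 4, size=n), rng.beta(2, 20, size=n))
    ds.add_channel("podocyte", np.clip(podo, 0, 1), score=True)

    if config.composition:
        names = list(config.composition)
        props = np.array([config.composition[k] for k in names])
        raw = props[None, :] + rng.normal(
            0.0, config.composition_noise_sd, size=(n, len(names))
        )
        raw = np.clip(raw, 0.0, 1.0)
        for j, name in enumerate(names):
            ds.add_channel(name, raw[:, j], score=True)
    return ds
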