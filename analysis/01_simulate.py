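"""Generate the synthetic study datasets.

Writes a clustered scRNA-seq count matrix (10x MTX trio) with planted
cluster markers, a doublet subpopulation, per-cell doublet scores and
mitochondrial fractions, two strain batches with one disease-enriched
cluster — plus a Visium-style spot grid with kidney-like anatomical
regions, a podocyte signature over glomeruli, two signature channels
correlated at rho=0.8 inside the cortex, and planted macrophage-subset
composition channels.

Run:  python analysis/01_simulate.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from nephromac import core_io
from nephromac.synthetic import (
    CellSimConfig,
    OutlierSpec,
    SpatialSimConfig,
    simulate_cells,
    simulate_spatial,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/simulated"))
args = parser.parse_args()

cells_dir = args.out / "cells"
spatial_dir = args.out / "spatial"
cells_dir.mkdir(parents=True, exist_ok=True)
spatial_dir.mkdir(parents=True, exist_ok=True)

cell_cfg = CellSimConfig(
    n_clusters=5, cells_per_cluster=100, n_genes=500,
    n_marker_genes_per_cluster=10, marker_fold_change=8.0,
    doublet_rate=0.05, doublet_cluster="DBL",
    outlier_cells=OutlierSpec(n_low_genes=5, n_high_genes=0, n_high_mito=5),
    seed=args.seed,
)
matrix, ann, markers = simulate_cells(cell_cfg)
core_io.write_counts_10x(
    matrix, cells_dir / "matrix.mtx", cells_dir / "features.tsv",
    cells_dir / "barcodes.tsv",
)
core_io.write_table(ann, cells_dir / "truth.tsv")
core_io.write_table(markers, cells_dir / "marker_genes.tsv")
print(
    f"cells: {matrix.n_cells} cells x {matrix.n_genes} genes, "
    f"{int(ann.is_doublet.sum())} doublets in cluster 'DBL', "
    f"{int((ann.strain == 'disease').sum())} disease-strain cells"
)

spatial_cfg = SpatialSimConfig(
    grid_rows=20, grid_cols=20,
    channel_pairs=[("ic_signature", "mnp_signature", "cortex", 0.8)],
    composition={"trmac_sig": 0.55, "momac_sig": 0.30, "dc_sig": 0.15},
    seed=args.seed,
)
ds = simulate_spatial(spatial_cfg)
core_io.write_spatial(
    ds, spatial_dir / "tissue_positions.csv", spatial_dir / "channels.tsv"
)
core_io.write_table(
    pd.DataFrame({"spot_id": ds.spot_ids, "region": ds.region}),
    spatial_dir / "truth.tsv",
)
counts = pd.Series(ds.region).value_counts()
print(f"spatial: {ds.n_spots} spots — " + ", ".join(f"{k}={v}" for k, v in counts.items()))
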