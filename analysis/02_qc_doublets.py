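"""QC, doublet-cluster flagging, filtering, normalization and HVG selection.

Reads the simulated count matrix from 01, flags clusters with outlying
median doublet scores (BH < 0.1), applies the standard cell/gene filters
(200-2,500 detected genes, mitochondrial fraction < 5%, genes in >= 3
cells), rescales every cell to the median total, and selects highly
variable genes.

Run after 01:  python analysis/02_qc_doublets.py
"""

import argparse
from pathlib import Path

from nephromac import core_io
from nephromac.preprocess import (
    QCParams,
    compute_qc,
    doublet_reports_to_frame,
    filter_cells_genes,
    flag_doublet_clusters,
    normalize_to_median,
    select_hvg,
)

parser = argparse.ArgumentParser()
parser.add_argument("--in-dir", type=Path, default=Path("results/simulated/cells"))
parser.add_argument("--out", type=Path, default=Path("results/preprocess"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

matrix = core_io.read_counts_10x(
    args.in_dir / "matrix.mtx", args.in_dir / "features.tsv",
    args.in_dir / "barcodes.tsv",
)
truth = core_io.read_table(args.in_dir / "truth.tsv")

reports = flag_doublet_clusters(
    truth["doublet_score"].to_numpy(), truth["true_cluster"].to_numpy()
)
core_io.write_table(doublet_reports_to_frame(reports), args.out / "doublet_clusters.tsv")
flagged = [r.cluster for r in reports if r.flagged]
print(f"doublet flagging: {flagged or 'no'} of {len(reports)} clusters flagged")

qc = compute_qc(matrix, "mt-")
core_io.write_table(qc, args.out / "qc_metrics.tsv")
filtered = filter_cells_genes(matrix, qc, QCParams())
normalized = normalize_to_median(filtered)
core_io.write_counts_10x(
    filtered, args.out / "matrix.mtx", args.out / "features.tsv",
    args.out / "barcodes.tsv",
)
hvg = select_hvg(normalized)
(args.out / "hvg.txt").write_text("".join(f"{g}\n" for g in hvg))
print(
    f"QC: kept {filtered.n_cells}/{matrix.n_cells} cells and "
    f"{filtered.n_genes}/{matrix.n_genes} genes; {len(hvg)} highly variable"
)
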