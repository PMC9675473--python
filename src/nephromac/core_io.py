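"""Shared data containers and readers/writers for the standard on-disk formats.

The pipeline touches three external formats: the 10x Genomics Matrix Market
trio (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``), GMT gene-set
files, and Visium-style ``tissue_positions.csv`` with per-spot score channels
in a TSV. Everything derived is written as TSV with a header row.

Conventions
-----------
* Gene identifiers are matched case-sensitively by exact string; no alias
  resolution.
* Missing values are NaN in memory and empty fields on disk.
* On-disk MTX is 1-based (Matrix Market standard); all in-memory indexing
  is 0-based.
* Readers never reorder: id order equals file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Input values violate a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x cells nonnegative matrix with identifiers and a layer tag.

    ``values`` is stored as a CSR sparse matrix; ``layer`` is ``"raw"`` for
    integer counts and ``"normalized"`` after median-target scaling.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.layer not in ("raw", "normalized"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell_ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("negative entries in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class GeneSet:
    """A named, duplicate-free list of gene identifiers."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicates")


@dataclass
class SpatialDataset:
    """Spots on an integer array grid with named per-spot score channels.

    ``channels`` maps channel name -> float vector aligned with ``spot_ids``.
    Prediction-score channels (label-transfer outputs) live in [0, 1];
    expression-derived channels are only required to be nonnegative. The
    distinction is declared per channel via ``score_channels``.
    """

    spot_ids: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    in_tissue: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    score_channels: set[str] = field(default_factory=set)
    expression: ExpressionMatrix | None = None
    region: np.ndarray | None = None  # truth labels from the simulator

    def __post_init__(self) -> None:
        n = len(self.spot_ids)
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        if len(set(self.spot_ids)) != n:
            raise ValidationError("duplicate spot ids")
        coords = set(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(coords) != n:
            raise ValidationError("duplicate spot coordinates")
        for name, vec in self.channels.items():
            vec = np.asarray(vec, dtype=float)
            self.channels[name] = vec
            if vec.shape != (n,):
                raise FormatError(f"channel {name!r} length != number of spots")
            self._check_channel_range(name, vec)

    def _check_channel_range(self, name: str, vec: np.ndarray) -> None:
        finite = vec[np.isfinite(vec)]
        if name in self.score_channels:
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValidationError(
                    f"prediction-score channel {name!r} outside [0, 1]"
                )
        elif finite.size and finite.min() < 0:
            raise ValidationError(f"channel {name!r} has negative values")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.array_row, self.array_col]).astype(float)

    def add_channel(self, name: str, values: np.ndarray, *, score: bool = False) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_spots,):
            raise FormatError(f"channel {name!r} length != number of spots")
        if score:
            self.score_channels.add(name)
        self._check_channel_range(name, values)
        self.channels[name] = values


# ---------------------------------------------------------------------------
# 10x MTX trio
# ---------------------------------------------------------------------------

def _read_id_column(path: str | Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts_10x(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a 10x-convention Matrix Market trio into a raw ExpressionMatrix.

    The on-disk orientation is genes x cells (cellranger convention); if the
    declared dimensions only match the id files transposed, the matrix is
    transposed so the in-memory contract is always genes x cells.
    """
    genes = _read_id_column(features_path)
    cells = _read_id_column(barcodes_path)
    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    if mat.shape == (len(genes), len(cells)):
        pass
    elif mat.shape == (len(cells), len(genes)) and len(genes) != len(cells):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix of shape {mat.shape} inconsistent with {len(genes)} "
            f"features and {len(cells)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("negative entries in count matrix")
    return ExpressionMatrix(mat, genes, cells, layer="raw")


def write_counts_10x(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(matrix.values))
    Path(features_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in matrix.cell_ids))


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gene_sets_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: one tab-separated line per set (name, description, genes...).

    Duplicate genes within a line are collapsed (first occurrence kept) with
    a warning; duplicate set names across lines are an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description, and at least one gene"
                )
            name = fields[0]
            if name in seen:
                raise FormatError(f"{path}: duplicate gene set name {name!r}")
            seen.add(name)
            genes = list(dict.fromkeys(fields[2:]))
            if len(genes) != len(fields) - 2:
                warnings.warn(
                    f"gene set {name!r}: duplicate genes collapsed", stacklevel=2
                )
            sets.append(GeneSet(name=name, genes=genes))
    return sets


def write_gene_sets_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Visium-style spatial data
# ---------------------------------------------------------------------------

POSITION_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


def read_spatial(
    positions_path: str | Path,
    channels_path: str | Path | None = None,
    *,
    score_channels: set[str] | None = None,
    tissue_only: bool = True,
) -> SpatialDataset:
    """Read a tissue-positions CSV plus an optional per-spot channels TSV.

    Positions follow the Visium ``tissue_positions`` convention
    (barcode, in_tissue, array_row, array_col, pixel coords); a header row is
    detected and skipped. Spots are restricted to ``in_tissue == 1`` unless
    ``tissue_only=False``. Channel barcodes must be a subset of position
    barcodes; spots without a channel record get NaN.
    """
    first = open(positions_path).readline()
    header = 0 if first.lower().startswith("barcode") else None
    pos = pd.read_csv(positions_path, header=header)
    pos.columns = POSITION_COLUMNS[: len(pos.columns)]
    if tissue_only:
        pos = pos[pos["in_tissue"].astype(int) == 1]
    ds = SpatialDataset(
        spot_ids=pos["barcode"].astype(str).tolist(),
        array_row=pos["array_row"].to_numpy(),
        array_col=pos["array_col"].to_numpy(),
        in_tissue=pos["in_tissue"].astype(int).to_numpy().astype(bool),
        score_channels=set(score_channels or set()),
    )
    if channels_path is not None:
        chan = pd.read_csv(channels_path, sep="\t")
        if "spot_id" not in chan.columns:
            raise FormatError("channels TSV must have a 'spot_id' column")
        unknown = set(chan["spot_id"].astype(str)) - set(ds.spot_ids)
        if unknown:
            raise FormatError(
                f"channel barcodes not present in positions: {sorted(unknown)[:5]}"
            )
        chan = chan.set_index("spot_id").reindex(ds.spot_ids)
        for name in chan.columns:
            ds.add_channel(
                name,
                chan[name].to_numpy(dtype=float),
                score=name in ds.score_channels,
            )
    return ds


def write_spatial(
    dataset: SpatialDataset,
    positions_path: str | Path,
    channels_path: str | Path | None = None,
) -> None:
    pos = pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "in_tissue": dataset.in_tissue.astype(int),
            "array_row": dataset.array_row,
            "array_col": dataset.array_col,
            "pxl_row_in_fullres": dataset.array_row,
            "pxl_col_in_fullres": dataset.array_col,
        }
    )
    pos.to_csv(positions_path, index=False)
    if channels_path is not None:
        chan = pd.DataFrame(dataset.channels, index=dataset.spot_ids)
        chan.index.name = "spot_id"
        # repr floats at full precision; NaN -> empty field
        chan.to_csv(channels_path, sep="\t", float_format="%.17g", na_rep="")


# ---------------------------------------------------------------------------
# generic TSV helpers for derived outputs
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
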