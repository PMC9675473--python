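"""Spot-neighborhood colocalization and glomerular composition analysis.

The colocalization statistic asks where two per-spot signals (gene-set
expression, signature prediction scores) co-vary across a tissue section:
for every spot a k-nearest neighborhood is formed on the array
coordinates, the correlation of the two channels is computed within each
neighborhood, and each spot is assigned the average correlation over all
neighborhoods that contain it. Non-positive averages are discarded
(rendered as missing / gray): the map highlights where the signals rise
and fall together, not where they diverge.

Glomerulus-containing spots are selected by thresholding a podocyte
signature channel; the composition of macrophage-subset signatures within
those spots is summarized as mean renormalized proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SpatialDataset, ValidationError


class EmptySelectionError(ValueError):
    """A selection rule matched no spot."""


@dataclass
class NeighborhoodParams:
    k: int = 7  # neighborhood size including the focal spot
    correlation: str = "pearson"  # or "spearman"
    # average over every neighborhood containing the spot (overlapping
    # windows); False averages only the spot's own neighborhood
    overlapping: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.correlation not in ("pearson", "spearman"):
            raise ValidationError("correlation must be 'pearson' or 'spearman'")


def build_knn(coords: np.ndarray, k: int) -> np.ndarray:
    """Per-spot neighborhood index sets (n_spots x k), focal spot first.

    Neighbors are the k-1 nearest spots by Euclidean distance on the array
    coordinates; distance ties break by ascending spot index (stable sort
    on the distance matrix), so the result is fully deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available spots")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")  # self (distance 0) first
    return order[:, :k]


def _neighborhood_r(a: np.ndarray, b: np.ndarray, method: str) -> float:
    """Correlation of two channel slices; NaN when either is constant."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    if method == "spearman":
        a = stats.rankdata(a)
        b = stats.rankdata(b)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return np.nan
    am = a - a.mean()
    bm = b - b.mean()
    denom = np.sqrt((am**2).sum() * (bm**2).sum())
    return float((am * bm).sum() / denom)


def neighborhood_correlation(
    dataset: SpatialDataset,
    chan_a: str,
    chan_b: str,
    params: NeighborhoodParams | None = None,
) -> pd.Series:
    """Per-spot averaged neighborhood correlation, positive values only.

    Steps: (1) the correlation r_N of the two channels is computed within
    every k-neighborhood N; r_N is missing when either channel is constant
    within N (no contrast to correlate); (2) each spot's score is the mean
    of r_N over all neighborhoods containing it, skipping missing r_N, and
    missing when all are; (3) scores <= 0 are set to missing — only
    positive colocalization is retained.

    Returns a float Series indexed by spot id; missing spots are NaN.
    """
    params = params or NeighborhoodParams()
    for name in (chan_a, chan_b):
        if name not in dataset.channels:
            raise ValidationError(f"channel {name!r} not present in the dataset")
    a = dataset.channels[chan_a]
    b = dataset.channels[chan_b]
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("channels must be complete (no missing values)")
    hoods = build_knn(dataset.coords(), params.k)
    n = dataset.n_spots
    r = np.array(
        [_neighborhood_r(a[idx], b[idx], params.correlation) for idx in hoods]
    )
    if params.overlapping:
        total = np.zeros(n)
        count = np.zeros(n)
        for focal in range(n):
            if np.isnan(r[focal]):
                continue
            for s in hoods[focal]:
                total[s] += r[focal]
                count[s] += 1
        with np.errstate(invalid="ignore"):
            score = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    else:
        score = r
    score = np.where(np.isnan(score) | (score <= 0), np.nan, score)
    return pd.Series(score, index=dataset.spot_ids, name=f"{chan_a}~{chan_b}")


@dataclass
class GlomSelectParams:
    channel: str = "podocyte"
    quantile: float | None = 0.95  # strict exceedance of this quantile
    threshold: float | None = None  # absolute threshold alternative

    def __post_init__(self) -> None:
        if self.quantile is not None and not 0 < self.quantile < 1:
            raise ValidationError("quantile must be in (0, 1)")
        if (self.quantile is None) == (self.threshold is None):
            raise ValidationError("set exactly one of quantile or threshold")


def select_glomerular_spots(
    dataset: SpatialDataset, params: GlomSelectParams | None = None
) -> list[str]:
    """Spot ids whose signature channel strictly exceeds the rule threshold."""
    params = params or GlomSelectParams()
    if params.channel not in dataset.channels:
        raise ValidationError(f"channel {params.channel!r} not present")
    vals = dataset.channels[params.channel]
    cut = (
        float(np.quantile(vals, params.quantile))
        if params.quantile is not None
        else float(params.threshold)
    )
    chosen = [s for s, v in zip(dataset.spot_ids, vals) if v > cut]
    if not chosen:
        raise EmptySelectionError(
            f"no spot exceeds {cut:.4g} on channel {params.channel!r}"
        )
    return chosen


def composition_in_spots(
    dataset: SpatialDataset,
    spot_set: list[str],
    subset_channels: list[str],
) -> tuple[pd.Series, int]:
    """Mean renormalized subset proportions over a spot selection.

    Each spot's listed channels are renormalized to sum to 1; spots where
    every listed channel is 0 are dropped (their count is returned). The
    result sums to 1 across subsets.

    Returns ``(proportions, n_dropped)``.
    """
    if not spot_set:
        raise ValidationError("spot_set is empty")
    for name in subset_channels:
        if name not in dataset.channels:
            raise ValidationError(f"channel {name!r} not present")
    idx = {s: i for i, s in enumerate(dataset.spot_ids)}
    missing = [s for s in spot_set if s not in idx]
    if missing:
        raise ValidationError(f"unknown spots in selection: {missing[:5]}")
    rows = np.array([idx[s] for s in spot_set])
    M = np.column_stack([dataset.channels[c][rows] for c in subset_channels])
    totals = M.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptySelectionError(
            "every selected spot has zero total across the listed subsets"
        )
    P = M[keep] / totals[keep, None]
    return pd.Series(P.mean(axis=0), index=subset_channels, name="proportion"), n_dropped
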