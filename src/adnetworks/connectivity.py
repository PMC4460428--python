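"""Mutual-information functional connectivity.

Statistical dependence between two regional time series is quantified by
the plug-in (histogram) mutual information

    MI(X, Y) = sum_{x,y} p(x, y) log2[ p(x, y) / (p(x) p(y)) ]

estimated from a joint histogram after marginal equiprobable (quantile)
binning of each series.  MI is reported in bits.  Quantile binning makes
the estimate invariant under monotone transforms of either series, which
matters because only the *ranking* of MI values feeds the downstream
density threshold.  No bias correction is applied: the plug-in positive
bias, roughly (b-1)^2 / (2 T ln 2) bits for b bins and T samples under
independence, is common to all pairs and so cannot reorder them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "default_n_bins",
    "mutual_information",
    "build_mi_matrix",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass
class TimeSeriesMatrix:
    """One subject's region x time signal array."""

    values: np.ndarray  # (n_regions, n_timepoints)
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series array must be 2-D (regions x time)")
        if self.values.shape[0] != len(self.region_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.region_ids)} region ids"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("time-series contains NaN or Inf")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative region x region dependence matrix.

    The diagonal is defined as 0 and is excluded from any thresholding.
    """

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not self.region_ids:
            self.region_ids = [f"R{i:03d}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("connectivity entries must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def default_n_bins(n_timepoints: int) -> int:
    """Histogram bin count used when none is given: ceil(sqrt(T/5)), clipped to [4, 16]."""
    return int(np.clip(math.ceil(math.sqrt(n_timepoints / 5)), 4, 16))


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each sample to a marginal equiprobable bin.

    Boundaries are linear-interpolation quantiles at 1/b .. (b-1)/b; a value
    equal to a boundary goes to the lower bin.
    """
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, x, side="left")


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """Plug-in mutual information of two series, in bits.

    A constant series occupies a single bin and yields MI = 0 (logged as
    degenerate).  The result is clamped at 0 against rounding.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain NaN or Inf")
    if n_bins is None:
        n_bins = default_n_bins(x.size)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} samples for {n_bins} bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("constant series: MI defined as 0")
        return 0.0
    bx = _bin_indices(x, n_bins)
    by = _bin_indices(y, n_bins)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).reshape(
        n_bins, n_bins
    ) / x.size
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(px, py)
    mi = float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))
    return max(mi, 0.0)


def build_mi_matrix(ts: TimeSeriesMatrix, n_bins: int | None = None) -> ConnectivityMatrix:
    """Mutual information for every unordered region pair.

    Vectorised: each region is expanded to a (n_bins, T) bin-indicator
    matrix; one matrix product yields every pairwise contingency table at
    once.  Entry (i, j) equals ``mutual_information(row i, row j)``.
    """
    if n_bins is None:
        n_bins = default_n_bins(ts.n_timepoints)
    if ts.n_timepoints < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} time points for {n_bins} bins")
    R, T = ts.n_regions, ts.n_timepoints
    constant = np.ptp(ts.values, axis=1) == 0
    if constant.any():
        logger.debug("%d constant region series: MI rows set to 0", constant.sum())

    bins = np.empty((R, T), dtype=np.intp)
    for i in range(R):
        bins[i] = _bin_indices(ts.values[i], n_bins)

    ind = np.zeros((R * n_bins, T))
    rows = np.repeat(np.arange(R), T) * n_bins + bins.ravel()
    ind[rows, np.tile(np.arange(T), R)] = 1.0
    counts = ind @ ind.T  # (R*b, R*b) pairwise bin co-occurrence
    joint = counts.reshape(R, n_bins, R, n_bins).transpose(0, 2, 1, 3) / T

    px = joint.sum(axis=3)  # (R, R, b): marginal of the row region
    py = joint.sum(axis=2)
    outer = px[:, :, :, None] * py[:, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(joint / outer), 0.0)
    mi = terms.sum(axis=(2, 3))
    mi = np.maximum(mi, 0.0)
    if constant.any():
        mi[constant, :] = 0.0
        mi[:, constant] = 0.0
    mi = (mi + mi.T) / 2.0  # symmetric up to float noise; enforce exactly
    np.fill_diagonal(mi, 0.0)
    return ConnectivityMatrix(mi, list(ts.region_ids))


# ---------------------------------------------------------------------------
# TSV round trips

def write_timeseries_tsv(ts: TimeSeriesMatrix, path) -> None:
    """Rows = regions in order; first column the region name, no header."""
    df = pd.DataFrame(ts.values)
    df.insert(0, "region", ts.region_ids)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


def read_timeseries_tsv(path) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t", header=None)
    region_ids = df.iloc[:, 0].astype(str).tolist()
    return TimeSeriesMatrix(df.iloc[:, 1:].to_numpy(dtype=float), region_ids)


def write_matrix_tsv(cm: ConnectivityMatrix, path) -> None:
    """Region ids as first row and first column."""
    df = pd.DataFrame(cm.values, index=cm.region_ids, columns=cm.region_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])
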