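"""Binary network construction at fixed density, plus the degree-outlier screen.

All subject networks keep the same number of edges, the top
``round(density * N(N-1)/2)`` connectivity values, so topological measures
are compared between groups of identical size: density = 2E / (N(N-1)).
An absolute-threshold variant supports the subject-exclusion screen, which
flags subjects whose total network degree falls outside Tukey fences
(Q1 - 1.5 IQR, Q3 + 1.5 IQR) across the cohort — very sparse networks
being suspected noise, very dense ones suspected artifact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BrainNetwork",
    "ExclusionReport",
    "threshold_to_density",
    "threshold_absolute",
    "detect_degree_outliers",
    "group_mean_network",
]


@dataclass
class BrainNetwork:
    """Undirected, binary, self-loop-free graph over named regions."""

    adjacency: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    density: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = A.astype(np.int8)
        if not self.region_ids:
            self.region_ids = [f"R{i:03d}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match adjacency")
        if not self.density:
            self.density = self.n_edges / max(n * (n - 1) / 2, 1)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.region_ids)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        G.add_edges_from(
            (self.region_ids[i], self.region_ids[j]) for i, j in zip(ii, jj)
        )
        return G

    @classmethod
    def from_networkx(cls, G: nx.Graph, region_ids: list[str] | None = None,
                      provenance: str = "") -> "BrainNetwork":
        ids = region_ids if region_ids is not None else [str(n) for n in G.nodes]
        A = nx.to_numpy_array(G, nodelist=ids, dtype=int)
        return cls(A, list(ids), provenance=provenance)

    def edge_list(self) -> pd.DataFrame:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return pd.DataFrame(
            {
                "region_a": [self.region_ids[i] for i in ii],
                "region_b": [self.region_ids[j] for j in jj],
            }
        )


@dataclass
class ExclusionReport:
    subject_id: str
    degree_total: int
    lower_fence: float
    upper_fence: float
    excluded: bool


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def threshold_to_density(C: ConnectivityMatrix, density: float,
                         provenance: str = "") -> BrainNetwork:
    """Keep the E = round(density * N(N-1)/2) strongest off-diagonal entries.

    Ties at the cutoff value are broken lexicographically by (i, j) region
    index — deterministic, and logged when they occur.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = C.n_regions
    n_pairs = n * (n - 1) // 2
    e_target = _round_half_away(density * n_pairs)
    if e_target == 0:
        raise ValueError(f"density {density} yields zero edges for N={n}")
    ii, jj = np.triu_indices(n, k=1)
    vals = C.values[ii, jj]
    # primary key: value descending; ties: (i, j) ascending
    order = np.lexsort((jj, ii, -vals))
    keep = order[:e_target]
    cutoff = vals[keep[-1]]
    n_at_cut = int((vals == cutoff).sum())
    if n_at_cut > 1 and e_target < n_pairs:
        logger.debug("density cutoff ties: %d pairs share value %.6g", n_at_cut, cutoff)
    A = np.zeros((n, n), dtype=np.int8)
    A[ii[keep], jj[keep]] = 1
    A += A.T
    return BrainNetwork(A, list(C.region_ids), density=density, provenance=provenance)


def threshold_absolute(C: ConnectivityMatrix, tau: float,
                       provenance: str = "") -> BrainNetwork:
    """Edge wherever connectivity >= tau; density back-computed from E."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = C.n_regions
    A = (C.values >= tau).astype(np.int8)
    np.fill_diagonal(A, 0)
    net = BrainNetwork(A, list(C.region_ids), provenance=provenance)
    if net.n_edges == 0:
        logger.debug("absolute threshold %.4g leaves an empty graph", tau)
    return net


def detect_degree_outliers(degrees, subject_ids=None) -> list[ExclusionReport]:
    """Tukey-fence screen on per-subject total network degree.

    Fences from linear-interpolation quartiles: a subject is excluded iff
    its degree lies below Q1 - 1.5 IQR or above Q3 + 1.5 IQR.
    """
    degrees = np.asarray(list(degrees), dtype=float)
    if degrees.size < 4:
        raise ValueError("need at least 4 subjects to set quartile fences")
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(degrees.size)]
    if len(subject_ids) != degrees.size:
        raise ValueError("subject_ids length does not match degrees")
    q1, q3 = np.quantile(degrees, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    reports = [
        ExclusionReport(sid, int(d), lo, hi, bool(d < lo or d > hi))
        for sid, d in zip(subject_ids, degrees)
    ]
    n_exc = sum(r.excluded for r in reports)
    if n_exc:
        logger.info("degree screen: %d of %d subjects outside fences [%.3g, %.3g]",
                    n_exc, degrees.size, lo, hi)
    return reports


def exclusion_table(reports: list[ExclusionReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def group_mean_network(Cs: list[ConnectivityMatrix], density: float,
                       provenance: str = "") -> BrainNetwork:
    """Element-wise mean of subject matrices, then density thresholding.

    How group-level networks should be aggregated from subject matrices is
    a genuine modelling choice; averaging the connectivity matrices before
    thresholding is ours (see the methods note).
    """
    if not Cs:
        raise ValueError("empty matrix list")
    ref = Cs[0].region_ids
    for c in Cs[1:]:
        if c.region_ids != ref:
            raise ValueError("all matrices must share region_ids in the same order")
    mean = np.mean([c.values for c in Cs], axis=0)
    return threshold_to_density(ConnectivityMatrix(mean, list(ref)), density,
                                provenance=provenance)
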