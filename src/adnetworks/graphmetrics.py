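"""Graph-theoretic measures of binary brain networks.

Seven whole-network measures are computed — characteristic path length,
clustering coefficient, global efficiency, local efficiency, betweenness
centrality (mean), assortativity, and modularity — together with nodal
forms (degree, clustering, local efficiency, betweenness, nodal global
efficiency) and their lobar averages.

Conventions on disconnected graphs: path length averages over reachable
ordered pairs only (their number is logged); efficiency measures treat an
unreachable pair as contributing 0 (1/inf), so they need no special
handling.  Betweenness uses the standard 2/((N-1)(N-2)) normalisation.
Assortativity is undefined when every node has the same degree; that case
raises :class:`DegenerateGraphError` rather than returning a number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import HEMISPHERES, LOBES, validate_lobe_map
from .netbuild import BrainNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateGraphError",
    "MetricsRecord",
    "characteristic_path_length",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "assortativity",
    "modularity",
    "lobar_average",
    "compute_metrics",
]

NODAL_METRICS = ("degree", "clustering", "local_eff", "betweenness", "nodal_global_eff")
WHOLE_BRAIN_METRICS = (
    "char_path_length",
    "clustering_coeff",
    "global_efficiency",
    "local_efficiency",
    "betweenness_mean",
    "assortativity",
    "modularity",
)


class DegenerateGraphError(ValueError):
    """A measure is mathematically undefined on this graph."""


def _as_graph(G) -> nx.Graph:
    if isinstance(G, BrainNetwork):
        return G.to_networkx()
    if isinstance(G, nx.Graph):
        return G
    raise TypeError(f"expected BrainNetwork or networkx Graph, got {type(G)}")


@dataclass
class MetricsRecord:
    """The seven whole-network measures plus nodal values for one network."""

    char_path_length: float
    clustering_coeff: float
    global_efficiency: float
    local_efficiency: float
    betweenness_mean: float
    assortativity: float  # NaN when undefined (regular graph)
    modularity: float
    nodal: pd.DataFrame = field(repr=False, default=None)  # region x NODAL_METRICS
    provenance: str = ""

    def whole_brain(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in WHOLE_BRAIN_METRICS},
                         name=self.provenance or None)


def characteristic_path_length(G) -> float:
    """Mean shortest-path length over reachable ordered pairs (self excluded)."""
    g = _as_graph(G)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    total, reachable = 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        total += sum(dists.values())
        reachable += len(dists) - 1  # drop the self distance
    if reachable == 0:
        raise DegenerateGraphError("no reachable pairs: path length undefined")
    skipped = n * (n - 1) - reachable
    if skipped:
        logger.debug("path length: %d unreachable ordered pairs excluded", skipped)
    return total / reachable


def clustering_coefficient(G):
    """(graph mean, per-node dict); nodes with degree < 2 score 0."""
    g = _as_graph(G)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodal = nx.clustering(g)
    return float(np.mean(list(nodal.values()))), nodal


def _efficiency_from_dists(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    nodal = {}
    for node, dists in nx.all_pairs_shortest_path_length(g):
        inv = sum(1.0 / d for t, d in dists.items() if t != node)
        nodal[node] = inv / (n - 1) if n > 1 else 0.0
    return nodal


def global_efficiency(G):
    """(graph value, per-node dict): mean over pairs of 1/d, 1/inf := 0."""
    g = _as_graph(G)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_nodes() == 1:
        return 0.0, {next(iter(g)): 0.0}
    nodal = _efficiency_from_dists(g)
    return float(np.mean(list(nodal.values()))), nodal


def local_efficiency(G):
    """(graph mean, per-node dict): nodal value is the global efficiency of
    the subgraph induced on the node's neighbours (0 for degree < 2)."""
    g = _as_graph(G)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodal = {}
    for node in g:
        nbrs = list(g[node])
        if len(nbrs) < 2:
            nodal[node] = 0.0
        else:
            nodal[node] = global_efficiency(g.subgraph(nbrs))[0]
    return float(np.mean(list(nodal.values()))), nodal


def betweenness_centrality(G):
    """(graph mean, per-node dict), fractional shortest-path counting,
    normalised by (N-1)(N-2)/2."""
    g = _as_graph(G)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodal = nx.betweenness_centrality(g, normalized=True)
    return float(np.mean(list(nodal.values()))), nodal


def assortativity(G) -> float:
    """Pearson correlation of endpoint degrees over edges (both orientations)."""
    g = _as_graph(G)
    if g.number_of_edges() < 2:
        raise DegenerateGraphError("assortativity needs at least 2 edges")
    deg = dict(g.degree())
    du, dv = [], []
    for u, v in g.edges():
        du += [deg[u], deg[v]]
        dv += [deg[v], deg[u]]
    du, dv = np.asarray(du, float), np.asarray(dv, float)
    if np.ptp(du) == 0:
        raise DegenerateGraphError("assortativity undefined: zero degree variance")
    return float(np.corrcoef(du, dv)[0, 1])


def _partition_modularity(g: nx.Graph, communities) -> float:
    return nx.community.modularity(g, communities)


def modularity(G, n_restarts: int = 20, seed: int = 0):
    """(best Q, partition) from seeded multilevel (Louvain) restarts.

    For graphs of up to 8 nodes the optimum is found by exhaustive search
    over all partitions instead — cheap, and exact.  Deterministic given
    ``seed``: restarts use seeds seed, seed+1, ...; the first partition
    attaining the best Q wins.
    """
    g = _as_graph(G)
    if g.number_of_edges() == 0:
        raise ValueError("modularity needs at least one edge")
    if g.number_of_nodes() <= 8:
        return _exact_modularity(g)
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        part = nx.community.louvain_communities(g, seed=seed + r)
        q = _partition_modularity(g, part)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    return float(best_q), [set(c) for c in best_part]


def _set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _exact_modularity(g: nx.Graph):
    nodes = list(g.nodes)
    best_q, best_part = -np.inf, None
    for part in _set_partitions(nodes):
        q = _partition_modularity(g, [set(c) for c in part])
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    return float(best_q), [set(c) for c in best_part]


def lobar_average(nodal_values: dict, lobe_map: pd.DataFrame) -> pd.Series:
    """Mean of nodal values within each lobe x hemisphere cell (10 cells).

    ``nodal_values`` maps region name -> value; every region must appear in
    the map, or a KeyError naming the region is raised.
    """
    regions = list(nodal_values)
    validate_lobe_map(lobe_map, regions)
    lk = lobe_map.set_index("region")
    rows = {}
    for region, value in nodal_values.items():
        lobe, hemi = lk.loc[region, "lobe"], lk.loc[region, "hemisphere"]
        rows.setdefault((lobe, hemi), []).append(value)
    cells = [(lobe, hemi) for lobe in LOBES for hemi in HEMISPHERES]
    out = pd.Series(
        {cell: float(np.mean(rows[cell])) for cell in cells if cell in rows},
        name="lobar_mean",
    )
    out.index = pd.MultiIndex.from_tuples(out.index, names=["lobe", "hemisphere"])
    return out


def compute_metrics(net: BrainNetwork, n_restarts: int = 20, seed: int = 0,
                    provenance: str | None = None) -> MetricsRecord:
    """All seven whole-network measures plus the nodal table for one network."""
    g = net.to_networkx()
    clus_mean, clus = clustering_coefficient(g)
    geff_mean, geff = global_efficiency(g)
    leff_mean, leff = local_efficiency(g)
    btw_mean, btw = betweenness_centrality(g)
    try:
        assort = assortativity(g)
    except DegenerateGraphError:
        logger.debug("assortativity undefined for %s", net.provenance or "network")
        assort = float("nan")
    q, _ = modularity(g, n_restarts=n_restarts, seed=seed)
    deg = dict(g.degree())
    nodal = pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "clustering": pd.Series(clus),
            "local_eff": pd.Series(leff),
            "betweenness": pd.Series(btw),
            "nodal_global_eff": pd.Series(geff),
        }
    ).loc[net.region_ids]
    return MetricsRecord(
        char_path_length=characteristic_path_length(g),
        clustering_coeff=clus_mean,
        global_efficiency=geff_mean,
        local_efficiency=leff_mean,
        betweenness_mean=btw_mean,
        assortativity=assort,
        modularity=q,
        nodal=nodal,
        provenance=provenance if provenance is not None else net.provenance,
    )
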