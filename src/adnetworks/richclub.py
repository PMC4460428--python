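"""Rich-club organization against degree-preserving random nulls.

The rich-club coefficient at degree threshold k is the edge density among
the nodes whose degree in the full graph is at least k:

    Phi(k) = 2 E_k / (N_k (N_k - 1))

where N_k counts the surviving nodes and E_k the edges among them.  The
degree filter is a single pass on the original degrees — no iterative
(k-core-style) re-computation after removal.  Because high-degree nodes
are mechanically more likely to share edges, Phi is normalised by the mean
coefficient of an ensemble of random networks with exactly the same degree
sequence, produced by repeated double-edge swaps (Maslov–Sneppen
rewiring); Phi_norm(k) > 1 with a small permutation p indicates rich-club
organisation beyond what the degree sequence alone enforces.  The
permutation p-value uses the add-one form (1 + #{null >= observed}) /
(1 + n_random), so it can never be exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netbuild import BrainNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "RichClubCurve",
    "rich_club_subgraph",
    "rich_club_coefficient",
    "rich_club_membership",
    "rewire_preserving_degree",
    "normalized_rich_club",
]


@dataclass
class RichClubCurve:
    """Phi, Phi_norm, permutation p and survivor counts over a k range.

    Entries where Phi is undefined (fewer than 2 surviving nodes, or the
    whole null ensemble undefined) carry NaN and are listed in
    ``undefined_k`` rather than silently dropped.
    """

    k_values: np.ndarray
    phi: np.ndarray
    phi_norm: np.ndarray
    perm_p: np.ndarray
    n_nodes_k: np.ndarray
    n_edges_k: np.ndarray
    n_random: int
    seed: int
    phi_random_mean: np.ndarray = field(default=None, repr=False)
    phi_random_sd: np.ndarray = field(default=None, repr=False)
    undefined_k: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "phi": self.phi,
                "phi_norm": self.phi_norm,
                "perm_p": self.perm_p,
                "n_nodes": self.n_nodes_k,
                "n_edges": self.n_edges_k,
            }
        )


def rich_club_subgraph(net: BrainNetwork, k: int):
    """(survivor node indices, edge count among them) at degree threshold k.

    Nodes with full-graph degree < k are removed together with their edges.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    deg = net.degrees()
    keep = np.flatnonzero(deg >= k)
    sub = net.adjacency[np.ix_(keep, keep)]
    return keep, int(sub.sum()) // 2


def rich_club_coefficient(net: BrainNetwork, k: int) -> float:
    """Phi(k) = 2 E_k / (N_k (N_k - 1)); NaN (flagged) below 2 survivors."""
    keep, n_edges = rich_club_subgraph(net, k)
    n = keep.size
    if n < 2:
        logger.debug("Phi(%d) undefined: %d surviving nodes", k, n)
        return float("nan")
    return 2.0 * n_edges / (n * (n - 1))


def rich_club_membership(net: BrainNetwork, k: int):
    """(region names, induced edge list DataFrame) of the k rich club."""
    keep, _ = rich_club_subgraph(net, k)
    names = [net.region_ids[i] for i in keep]
    sub = net.adjacency[np.ix_(keep, keep)]
    ii, jj = np.nonzero(np.triu(sub, k=1))
    edges = pd.DataFrame(
        {"region_a": [names[i] for i in ii], "region_b": [names[j] for j in jj]}
    )
    return names, edges


def rewire_preserving_degree(net: BrainNetwork, n_swaps: int, seed: int,
                             max_tries_per_swap: int = 100) -> BrainNetwork:
    """Randomise edges by double-edge swaps; degree sequence exactly kept.

    Each swap picks two edges (a,b), (c,d) and replaces them with (a,d),
    (c,b) when that creates neither a self-loop nor a duplicate edge.
    Runs until ``n_swaps`` successful swaps or the attempt budget
    (``max_tries_per_swap * n_swaps + 100``) is exhausted — graphs with no
    swappable pair (e.g. a 2-edge path) come back unchanged, logged.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be nonnegative")
    rng = np.random.default_rng(seed)
    A = net.adjacency.copy()
    ii, jj = np.nonzero(np.triu(A, k=1))
    edges = np.stack([ii, jj], axis=1)
    m = edges.shape[0]
    if m < 2 or n_swaps == 0:
        if m < 2:
            logger.debug("rewiring skipped: fewer than 2 edges")
        return BrainNetwork(A, list(net.region_ids), provenance=net.provenance)
    done, tries = 0, 0
    budget = max_tries_per_swap * n_swaps + 100
    while done < n_swaps and tries < budget:
        tries += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(0, 2):  # random orientation of the second edge
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, d] = A[d, a] = 1
        A[c, b] = A[b, c] = 1
        edges[e1] = sorted((a, d))
        edges[e2] = sorted((c, b))
        done += 1
    if done < n_swaps:
        logger.debug("rewiring stopped at %d/%d swaps after %d attempts",
                     done, n_swaps, tries)
    return BrainNetwork(A, list(net.region_ids), provenance=net.provenance)


def normalized_rich_club(net: BrainNetwork, k_values=range(1, 16),
                         n_random: int = 1000, seed: int = 0,
                         swap_factor: int = 10) -> RichClubCurve:
    """Phi, Phi_norm = Phi / mean(null Phi), and permutation p over k.

    The null ensemble holds ``n_random`` degree-preserving rewirings of the
    observed graph, each using ``swap_factor * E`` successful double-edge
    swaps (``swap_factor=0`` keeps the graph itself — an identity null).
    Phi_random(k) is the ensemble mean over nulls where Phi is defined;
    perm_p(k) = (1 + #{null Phi >= observed Phi}) / (1 + n_random).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    k_values = np.asarray(list(k_values), dtype=int)
    phi = np.array([rich_club_coefficient(net, int(k)) for k in k_values])
    counts = np.array([rich_club_subgraph(net, int(k))[0].size for k in k_values])
    edges_k = np.array([rich_club_subgraph(net, int(k))[1] for k in k_values])

    rng = np.random.default_rng(seed)
    n_swaps = swap_factor * net.n_edges
    null_phi = np.full((n_random, k_values.size), np.nan)
    for r in range(n_random):
        null_seed = int(rng.integers(0, 2**31 - 1))
        null = rewire_preserving_degree(net, n_swaps, seed=null_seed)
        null_phi[r] = [rich_club_coefficient(null, int(k)) for k in k_values]

    with np.errstate(invalid="ignore"):
        phi_rand = np.nanmean(null_phi, axis=0)
        phi_rand_sd = np.nanstd(null_phi, axis=0)
    phi_norm = np.full_like(phi, np.nan)
    perm_p = np.full_like(phi, np.nan)
    undefined = []
    for idx, k in enumerate(k_values):
        if np.isnan(phi[idx]) or np.isnan(phi_rand[idx]) or phi_rand[idx] == 0:
            undefined.append(int(k))
            continue
        phi_norm[idx] = phi[idx] / phi_rand[idx]
        defined_nulls = null_phi[:, idx][~np.isnan(null_phi[:, idx])]
        ge = int((defined_nulls >= phi[idx] - 1e-12).sum())
        perm_p[idx] = (1 + ge) / (1 + defined_nulls.size)
    if undefined:
        logger.debug("Phi_norm undefined at k=%s", undefined)
    return RichClubCurve(
        k_values=k_values,
        phi=phi,
        phi_norm=phi_norm,
        perm_p=perm_p,
        n_nodes_k=counts,
        n_edges_k=edges_k,
        n_random=n_random,
        seed=seed,
        phi_random_mean=phi_rand,
        phi_random_sd=phi_rand_sd,
        undefined_k=undefined,
    )


def planted_rich_club_graph(k: int, n_nodes: int, n_edges: int,
                            region_prefix: str = "R") -> BrainNetwork:
    """Construct a graph whose degree->=k rich club has exactly the given size.

    ``n_edges`` edges are laid out circulant-fashion among ``n_nodes`` core
    nodes (spreading internal degree as evenly as possible); core nodes
    whose degree falls short of k are then padded with spokes to periphery
    nodes, each periphery node accepting at most k-1 spokes so that no
    periphery node survives the degree filter.  Useful for planting
    rich-club configurations with known (N_k, E_k).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 core nodes")
    max_core = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_core:
        raise ValueError(f"{n_edges} edges exceed the {max_core} core pairs")
    core_edges = set()
    offset = 1
    while len(core_edges) < n_edges and offset <= n_nodes // 2:
        for i in range(n_nodes):
            j = (i + offset) % n_nodes
            core_edges.add((min(i, j), max(i, j)))
            if len(core_edges) == n_edges:
                break
        offset += 1
    if len(core_edges) < n_edges:  # dense remainder beyond circulant reach
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                core_edges.add((i, j))
                if len(core_edges) == n_edges:
                    break
            if len(core_edges) == n_edges:
                break
    deg = np.zeros(n_nodes, dtype=int)
    for i, j in core_edges:
        deg[i] += 1
        deg[j] += 1
    spokes_needed = [(i, k - d) for i, d in enumerate(deg) if d < k]
    total_spokes = sum(s for _, s in spokes_needed)
    per_periph = max(k - 1, 1)
    n_periph = 0
    if total_spokes:
        # enough periphery capacity, and enough distinct nodes that a core
        # node's spokes (assigned to consecutive periphery slots, cyclically)
        # never repeat a pair
        n_periph = max(-(-total_spokes // per_periph),
                       max(s for _, s in spokes_needed))
    n_total = n_nodes + n_periph
    A = np.zeros((n_total, n_total), dtype=np.int8)
    for i, j in core_edges:
        A[i, j] = A[j, i] = 1
    slot = 0
    for i, need in spokes_needed:
        for _ in range(need):
            periph = n_nodes + slot % n_periph
            A[i, periph] = A[periph, i] = 1
            slot += 1
    ids = [f"{region_prefix}{i:03d}" for i in range(n_total)]
    return BrainNetwork(A, ids, provenance=f"planted_rich_club_k{k}")
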