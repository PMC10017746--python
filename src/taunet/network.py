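"""The individualized weighted network and its strength/efficiency metrics.

The network is fully connected and undirected: the edge weight between
nodes i and j is the absolute difference of their node-mean SUVRs,

    w_ij = |x̄_i − x̄_j|,

so a larger between-region difference in tau burden is a *stronger* edge.
Network distance is the inverse weight, d_ij = 1/w_ij (infinite when the
means coincide), and shortest-path lengths allow multi-hop routes — an
indirect path through a high-burden node can be shorter than the direct
link. Three summary measures follow:

* nodal strength   s_i = Σ_j w_ij  (sum of incident weights),
* global strength  mean of s_i over all nodes (limbic strength: the mean
  over the bilateral amygdala + parahippocampal nodes only),
* global efficiency  E^w = (1/n) Σ_i Σ_{j≠i} (d*_ij)^{-1} / (n−1), the mean
  inverse shortest-path length; unreachable pairs contribute 0.

All quantities carry SUVR-difference units: adding a constant to the
profile changes nothing, scaling it by c > 0 scales every measure by c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .nodes import NodeSet, RegionalProfile

__all__ = [
    "TauNetwork",
    "NetworkMeasures",
    "build_network",
    "weights_to_distances",
    "shortest_paths",
    "nodal_strength",
    "global_efficiency",
    "network_measures",
    "proportional_threshold",
]


@dataclass
class TauNetwork:
    """Symmetric nonnegative weight matrix over the included nodes."""

    node_ids: list[int]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} does not match {n} nodes")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class NetworkMeasures:
    global_efficiency: float
    global_strength: float
    limbic_strength: float | None
    nodal_strengths: np.ndarray
    node_ids: list[int]


def build_network(profile: RegionalProfile) -> TauNetwork:
    """Pairwise absolute differences of the node means."""
    x = profile.values
    if x.size < 2:
        raise ValueError("need at least 2 nodes to build a network")
    w = np.abs(x[:, None] - x[None, :])
    np.fill_diagonal(w, 0.0)
    return TauNetwork(node_ids=list(profile.node_ids), weights=w)


def weights_to_distances(net: TauNetwork) -> np.ndarray:
    """Direct network distances 1/w_ij; +inf where w_ij = 0 off-diagonal."""
    w = net.weights
    with np.errstate(divide="ignore"):
        d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def shortest_paths(direct: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths (Dijkstra per source).

    ``direct`` is a dense direct-distance matrix with +inf for absent edges
    and zero diagonal. Unreachable pairs stay +inf.
    """
    direct = np.asarray(direct, dtype=float)
    if np.any(direct < 0):
        raise ValueError("distances must be nonnegative")
    # csgraph's dense representation uses 0 for "no edge"; genuine direct
    # distances are strictly positive, so inf -> 0 is unambiguous here.
    dense = np.where(np.isfinite(direct), direct, 0.0)
    np.fill_diagonal(dense, 0.0)
    return _csgraph_shortest_path(dense, method="D", directed=False)


def nodal_strength(net: TauNetwork) -> np.ndarray:
    """s_i = sum of all weights incident to node i."""
    return net.weights.sum(axis=1)


def global_efficiency(net: TauNetwork) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_paths(weights_to_distances(net))
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def proportional_threshold(net: TauNetwork, density: float) -> TauNetwork:
    """Keep the strongest `density` fraction of edges, zeroing the rest.

    Optional robustness-check variant; the default analysis uses the full
    weighted network.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    w = net.weights.copy()
    iu = np.triu_indices_from(w, k=1)
    edge_w = w[iu]
    k = int(np.ceil(density * edge_w.size))
    if k < edge_w.size:
        cutoff = np.sort(edge_w)[::-1][k - 1]
        keep = w >= cutoff
        w = np.where(keep, w, 0.0)
        np.fill_diagonal(w, 0.0)
    return TauNetwork(node_ids=list(net.node_ids), weights=w)


def network_measures(
    profile: RegionalProfile,
    node_set: NodeSet | None = None,
    limbic_ids: Iterable[int] | None = None,
) -> NetworkMeasures:
    """Bundle global efficiency, global strength and limbic strength.

    Limbic ids come from ``limbic_ids`` if given, else from the node set;
    if neither supplies any, limbic strength is None.
    """
    net = build_network(profile)
    s = nodal_strength(net)
    gs = float(s.mean())
    eff = global_efficiency(net)

    if limbic_ids is None and node_set is not None:
        limbic_ids = node_set.limbic_ids
    limbic = None
    if limbic_ids:
        wanted = [int(i) for i in limbic_ids]
        index = {rid: k for k, rid in enumerate(net.node_ids)}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise ValueError(f"limbic node ids missing from profile: {missing}")
        limbic = float(np.mean([s[index[i]] for i in wanted]))
    return NetworkMeasures(
        global_efficiency=eff,
        global_strength=gs,
        limbic_strength=limbic,
        nodal_strengths=s,
        node_ids=list(net.node_ids),
    )
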