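"""Barabasi-Albert scale-free networks guiding the bee-colony search.

The network is built once per run: an initial complete clique of m0 hub
nodes, then one node at a time, each attaching ``n_links`` distinct edges
to existing nodes with probability proportional to current degree
(preferential attachment).  Node ids are 1-based: the hubs occupy ids
1..m0 in random order and later nodes take ids m0+1.. in join order, so
the optimizer can map its fitness-sorted population directly onto node
ids (best solutions on the hubs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaleFreeNetwork",
    "build_ba_network",
    "max_degree_neighbor",
    "degree_distribution",
    "edge_list",
]


@dataclass
class ScaleFreeNetwork:
    """Immutable BA graph over 1-based node ids 1..n_nodes."""

    n_nodes: int
    m0: int
    n_links: int
    adjacency: dict[int, frozenset[int]]
    hub_ids: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.hub_ids:
            self.hub_ids = tuple(range(1, self.m0 + 1))

    @property
    def degrees(self) -> dict[int, int]:
        return {node: len(nbrs) for node, nbrs in self.adjacency.items()}

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adjacency.values()) // 2

    def structural_hash(self) -> int:
        """Order-independent fingerprint of the edge set (mutation guard)."""
        return hash(frozenset(
            (min(a, b), max(a, b))
            for a, nbrs in self.adjacency.items()
            for b in nbrs
        ))


def build_ba_network(n_nodes: int, m0: int, n_links: int, seed: int) -> ScaleFreeNetwork:
    """Grow a BA network: complete clique on m0 nodes, then preferential
    attachment of ``n_links`` distinct edges per new node.

    Duplicate targets are resampled, so the graph stays simple.  The m0
    clique nodes receive ids 1..m0 in random order; every later node gets
    the next id in join order.  Reproducible from ``seed``.
    """
    if not (1 <= n_links < m0 <= n_nodes):
        raise ValueError(
            f"need 1 <= n_links < m0 <= n_nodes, got n_links={n_links}, "
            f"m0={m0}, n_nodes={n_nodes}"
        )
    rng = np.random.default_rng(seed)

    hub_ids = tuple(int(i) for i in rng.permutation(np.arange(1, m0 + 1)))
    adjacency: dict[int, set[int]] = {i: set() for i in range(1, n_nodes + 1)}
    for a in hub_ids:
        for b in hub_ids:
            if a != b:
                adjacency[a].add(b)

    # endpoint multiset: sampling uniformly from it is degree-proportional
    endpoints: list[int] = [node for node in hub_ids for _ in range(m0 - 1)]
    for new in range(m0 + 1, n_nodes + 1):
        targets: set[int] = set()
        while len(targets) < n_links:
            targets.add(endpoints[rng.integers(len(endpoints))])
        for t in sorted(targets):
            adjacency[new].add(t)
            adjacency[t].add(new)
            endpoints.append(t)
            endpoints.append(new)

    return ScaleFreeNetwork(
        n_nodes=n_nodes,
        m0=m0,
        n_links=n_links,
        adjacency={n: frozenset(nbrs) for n, nbrs in adjacency.items()},
        hub_ids=hub_ids,
    )


def max_degree_neighbor(net: ScaleFreeNetwork, node: int) -> int:
    """The neighbor of ``node`` with maximal degree; ties go to the
    smallest node id.  Never returns ``node`` itself."""
    try:
        nbrs = net.adjacency[node]
    except KeyError:
        raise KeyError(f"node {node} not in network") from None
    if not nbrs:
        raise ValueError(f"node {node} is isolated")
    return min(nbrs, key=lambda b: (-len(net.adjacency[b]), b))


def degree_distribution(net: ScaleFreeNetwork) -> tuple[dict[int, float], float]:
    """Empirical degree distribution P_k and a fitted power-law exponent.

    gamma_hat is minus the slope of the least-squares fit of ln P_k on
    ln k over degrees k >= n_links with P_k > 0 (diagnostic only; the
    search never uses it).  Returns (P_k, gamma_hat); gamma_hat is NaN
    when fewer than two degree classes are available for the fit.
    """
    degs = np.array([len(nbrs) for nbrs in net.adjacency.values()])
    ks, counts = np.unique(degs, return_counts=True)
    pk = {int(k): float(c) / net.n_nodes for k, c in zip(ks, counts)}
    mask = ks >= net.n_links
    if mask.sum() < 2:
        return pk, float("nan")
    x = np.log(ks[mask].astype(float))
    y = np.log(counts[mask] / net.n_nodes)
    slope = np.polyfit(x, y, 1)[0]
    return pk, float(-slope)


def edge_list(net: ScaleFreeNetwork) -> list[tuple[int, int]]:
    """Sorted (a, b) edge pairs with a < b, e.g. for TSV export."""
    return sorted(
        {(min(a, b), max(a, b)) for a, nbrs in net.adjacency.items() for b in nbrs}
    )
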