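"""Graph data model and topological primitives.

The central container is :class:`InteractionNetwork`, a thin wrapper around
an undirected :class:`networkx.Graph` that fixes a canonical node order
(ascending node identifier).  All vectors and matrices produced elsewhere in
the package (seed vectors, propagation scores, transition matrices) are
aligned to this order, so the order is part of the public contract.

Topological primitives implemented here:

* largest connected component extraction (with a deterministic tie-break),
* k-core numbers (coreness) via iterative minimum-degree peeling,
* the coreness-normalized column-stochastic transition matrix used by the
  random walk with restart, and
* the core-clustering coefficient (edge density of the densest k-core of a
  node's closed neighborhood, the MCODE statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "InteractionNetwork",
    "Module",
    "largest_connected_component",
    "coreness",
    "core_normalized_transition",
    "core_clustering_coefficient",
]


class InteractionNetwork:
    """Undirected simple graph over gene identifiers with a fixed node order.

    Self-loops are dropped and parallel edges collapsed on construction.
    Node identifiers are coerced to ``str``; the canonical node order is
    ascending lexicographic on the identifier.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v)`` or ``(u, v, confidence)`` tuples, or an
        existing :class:`networkx.Graph`.
    nodes:
        Optional extra node identifiers (isolated nodes are permitted in the
        container; operations that require connectivity check for it).
    """

    def __init__(self, edges=(), nodes: Iterable[str] = ()):
        if isinstance(edges, nx.Graph):
            g = nx.Graph()
            g.add_nodes_from(str(n) for n in edges.nodes)
            for u, v, data in edges.edges(data=True):
                if str(u) == str(v):
                    continue
                g.add_edge(str(u), str(v), **data)
        else:
            g = nx.Graph()
            for e in edges:
                u, v = str(e[0]), str(e[1])
                if u == v:
                    continue
                if len(e) > 2:
                    g.add_edge(u, v, confidence=float(e[2]))
                else:
                    g.add_edge(u, v)
        g.add_nodes_from(str(n) for n in nodes)
        self._graph = g
        self._nodes = tuple(sorted(g.nodes))
        self._index = {v: i for i, v in enumerate(self._nodes)}

    # -- basic accessors ---------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        """Canonical node order (ascending identifier)."""
        return self._nodes

    @property
    def index(self) -> Mapping[str, int]:
        return self._index

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def degree(self, node: str) -> int:
        return self._graph.degree[node]

    def neighbors(self, node: str) -> list[str]:
        return sorted(self._graph.neighbors(node))

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._graph)

    def subnetwork(self, nodes: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on ``nodes`` as a new network."""
        nodes = [str(n) for n in nodes]
        missing = [n for n in nodes if n not in self._index]
        if missing:
            raise KeyError(f"nodes not in network: {missing[:5]}")
        return InteractionNetwork(self._graph.subgraph(nodes).copy())

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Adjacency matrix in canonical node order (CSR).

        With ``weighted=True`` the per-edge ``confidence`` attribute is used
        (missing confidences default to 1).
        """
        weight = "confidence" if weighted else None
        return nx.to_scipy_sparse_array(
            self._graph, nodelist=self._nodes, weight=weight, format="csr"
        )

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as sorted (u < v) pairs, in ascending order."""
        return sorted(tuple(sorted(e)) for e in self._graph.edges)

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class Module:
    """A connected node subset of a parent network, with provenance.

    ``nodes`` is stored in canonical (ascending) order.  ``score`` is the
    network score (mean standardized ECI x mean core-clustering coefficient)
    assigned by the engine; ``iteration``, ``alpha`` and ``filtering_rate``
    record where in the run the module was produced.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    score: float = float("nan")
    iteration: int = 0
    alpha: float = float("nan")
    filtering_rate: float = float("nan")

    @classmethod
    def from_nodes(
        cls,
        net: InteractionNetwork,
        nodes: Iterable[str],
        score: float = float("nan"),
        iteration: int = 0,
        alpha: float = float("nan"),
        filtering_rate: float = float("nan"),
    ) -> "Module":
        nodes = tuple(sorted(str(n) for n in nodes))
        if not nodes:
            raise ValueError("module must be non-empty")
        sub = net.graph.subgraph(nodes)
        if len(nodes) > 1 and not nx.is_connected(sub):
            raise ValueError("module induced subgraph is not connected")
        edges = tuple(sorted(tuple(sorted(e)) for e in sub.edges))
        return cls(nodes, edges, score, iteration, alpha, filtering_rate)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def subnetwork(self, net: InteractionNetwork) -> InteractionNetwork:
        return net.subnetwork(self.nodes)


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Largest connected component; ties broken by smallest member identifier.

    Emits a :class:`UserWarning` stating how many nodes were dropped.
    """
    if net.n_nodes == 0:
        raise ValueError("empty graph has no connected component")
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    keep = comps[0]
    dropped = net.n_nodes - len(keep)
    if dropped:
        warnings.warn(
            f"largest connected component kept {len(keep)} nodes; "
            f"{dropped} nodes in smaller components dropped",
            stacklevel=2,
        )
        return net.subnetwork(keep)
    return net


def coreness(net: InteractionNetwork) -> dict[str, int]:
    """k-core number per node (iterative minimum-degree peeling)."""
    return {v: int(k) for v, k in nx.core_number(net.graph).items()}


def core_normalized_transition(net: InteractionNetwork) -> sp.csr_matrix:
    """Column-stochastic transition matrix normalized by node coreness.

    Entry (i, j) is ``k_i / sum_l k_l`` over the neighbors ``l`` of ``j``,
    where ``k`` is the k-core number; zero elsewhere.  Column j is the
    distribution of a walker stepping away from node j, so high-coreness
    neighbors attract proportionally more probability than under plain
    degree normalization.
    """
    if net.n_nodes < 2:
        raise ValueError("transition matrix requires at least 2 nodes")
    if not net.is_connected():
        raise ValueError("transition matrix requires a connected graph")
    core = coreness(net)
    k = np.array([core[v] for v in net.nodes], dtype=float)
    adj = net.adjacency().astype(float)
    # scale rows by coreness, then normalize columns
    m = sp.diags(k) @ adj
    colsum = np.asarray(m.sum(axis=0)).ravel()
    if np.any(colsum <= 0):
        raise ValueError("graph has an isolated node (zero transition column)")
    return (m @ sp.diags(1.0 / colsum)).tocsr()


def core_clustering_coefficient(net: InteractionNetwork, v: str) -> float:
    """Edge density of the densest k-core of the closed neighborhood of ``v``.

    The closed neighborhood is ``v`` plus its neighbors (MCODE convention).
    The k-core with the largest k of that induced subgraph is taken and its
    edge density ``2E / (n (n - 1))`` returned; a single-node neighborhood
    has density 0 by convention.
    """
    if v not in net:
        raise KeyError(f"node {v!r} not in network")
    closed = [v] + list(net.graph.neighbors(v))
    sub = net.graph.subgraph(closed)
    if sub.number_of_edges() == 0:
        return 0.0
    core_num = nx.core_number(sub)
    kmax = max(core_num.values())
    core_nodes = [u for u, c in core_num.items() if c >= kmax]
    core_sub = sub.subgraph(core_nodes)
    n = core_sub.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * core_sub.number_of_edges() / (n * (n - 1))
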