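"""Maximum-weight connected subgraph (MWCS) solvers on signed node weights.

Given a connected graph whose nodes carry signed weights (here: quantile-
shifted propagation scores), the MWCS problem asks for a connected node
subset of maximum total weight.  The exact problem is NP-hard; this module
provides

* :func:`heinz_heuristic` — a spanning-tree heuristic in the spirit of the
  heaviest-induced-subgraph family: connected components of positive-weight
  nodes are contracted to meta-nodes, meta-nodes are joined by cheapest
  paths through negative nodes, a minimum spanning tree of the resulting
  meta-graph is pruned leaf-by-leaf while unprofitable, and the survivors
  are expanded back to original nodes; and
* :func:`mwcs_exact` — exhaustive enumeration of connected induced
  subgraphs, feasible up to 16 nodes, used as the test oracle.

All tie-breaks are by ascending node identifier, so both solvers are
deterministic functions of the input.
"""

from __future__ import annotations

import heapq
from itertools import count
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .diffusion import ShiftedWeights
from .network import InteractionNetwork, Module

__all__ = ["heinz_heuristic", "mwcs_exact"]


def _weight_map(net: InteractionNetwork, weights) -> dict[str, float]:
    w = weights.weights if isinstance(weights, ShiftedWeights) else np.asarray(weights, dtype=float)
    if len(w) != net.n_nodes:
        raise ValueError("weights not aligned to network node order")
    return {v: float(w[i]) for i, v in enumerate(net.nodes)}


def _positive_components(net: InteractionNetwork, w: Mapping[str, float]):
    """Connected components of the positive-weight induced subgraph, sorted."""
    pos = [v for v in net.nodes if w[v] > 0]
    comps = [sorted(c) for c in nx.connected_components(net.graph.subgraph(pos))]
    comps.sort(key=lambda c: c[0])
    return comps


def _dijkstra_node_cost(
    graph: nx.Graph, sources: Sequence[str], penalty: Mapping[str, float]
):
    """Shortest paths where entering node v costs ``penalty[v]``.

    Returns dist and predecessor maps; the source entry cost is excluded.
    Ties are resolved toward lexicographically smaller paths by using the
    node id as a secondary heap key.
    """
    dist: dict[str, float] = {}
    pred: dict[str, str | None] = {}
    tick = count()
    heap = [(0.0, s, next(tick), None) for s in sorted(sources)]
    heapq.heapify(heap)
    while heap:
        d, v, _, parent = heapq.heappop(heap)
        if v in dist:
            continue
        dist[v] = d
        pred[v] = parent
        for u in sorted(graph.neighbors(v)):
            if u not in dist:
                heapq.heappush(heap, (d + penalty[u], u, next(tick), v))
    return dist, pred


def heinz_heuristic(net: InteractionNetwork, weights) -> Module:
    """Heuristic maximum-weight connected subgraph on signed node weights.

    The returned module is always connected, always contains at least the
    heaviest single positive meta-node's worth of weight, and includes every
    positive component reachable from the selection at zero cost.

    Raises
    ------
    ValueError
        If the input graph is disconnected or no node has positive weight
        (the filtering rate drove every weight non-positive).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if not net.is_connected():
        raise ValueError("MWCS input graph must be connected")
    w = _weight_map(net, weights)
    comps = _positive_components(net, w)
    if not comps:
        raise ValueError("no node with positive weight; filtering rate too aggressive")

    meta_members = {f"M{i:06d}": tuple(c) for i, c in enumerate(comps)}
    meta_weight = {m: sum(w[v] for v in members) for m, members in meta_members.items()}
    heaviest = min(meta_weight, key=lambda m: (-meta_weight[m], meta_members[m][0]))

    if len(meta_members) == 1:
        selected = set(meta_members[heaviest])
        return _finalize(net, w, selected, meta_members)

    # Contracted graph: each positive component becomes one vertex; negative
    # and zero-weight nodes stay as themselves.  Entering a negative node
    # costs |weight|; meta and zero nodes are free.
    node2meta: dict[str, str] = {}
    for m, members in meta_members.items():
        for v in members:
            node2meta[v] = m
    contracted = nx.Graph()
    contracted.add_nodes_from(meta_members)
    penalty: dict[str, float] = {m: 0.0 for m in meta_members}
    for v in net.nodes:
        if v not in node2meta:
            contracted.add_node(v)
            penalty[v] = max(0.0, -w[v])
    for u, v in net.graph.edges:
        cu, cv = node2meta.get(u, u), node2meta.get(v, v)
        if cu != cv:
            contracted.add_edge(cu, cv)

    # Cheapest connector path between every pair of meta-nodes.
    path_cost: dict[tuple[str, str], float] = {}
    path_nodes: dict[tuple[str, str], tuple[str, ...]] = {}
    metas = sorted(meta_members)
    for m in metas:
        dist, pred = _dijkstra_node_cost(contracted, [m], penalty)
        for m2 in metas:
            if m2 <= m or m2 not in dist:
                continue
            interior = []
            cur = pred[m2]
            while cur is not None and cur != m:
                interior.append(cur)
                cur = pred[cur]
            path_cost[(m, m2)] = dist[m2]
            path_nodes[(m, m2)] = tuple(reversed(interior))

    # Minimum spanning tree of the meta-graph under
    # cost(path) - (weight of the two incident meta-nodes); Kruskal with
    # deterministic (cost, id, id) ordering.
    edges = sorted(
        (cost - meta_weight[a] - meta_weight[b], a, b)
        for (a, b), cost in path_cost.items()
    )
    parent = {m: m for m in metas}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = nx.Graph()
    tree.add_nodes_from(metas)
    for cost, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.add_edge(a, b, path_cost=path_cost[(a, b)])

    # Prune unprofitable leaves: a leaf whose connector costs more than the
    # meta-node weight it brings is removed; worst offender first, ties
    # resolved so smaller node identifiers survive.
    while tree.number_of_nodes() > 1:
        candidates = []
        for leaf in tree.nodes:
            if tree.degree[leaf] != 1:
                continue
            (edge,) = tree.edges(leaf)
            cost = tree.edges[edge]["path_cost"]
            surplus = cost - meta_weight[leaf]
            if surplus > 0:
                candidates.append((surplus, meta_members[leaf][0], leaf))
        if not candidates:
            break
        # worst surplus first; on ties prune the larger member id so smaller
        # identifiers survive (two stable sorts)
        candidates.sort(key=lambda t: t[1], reverse=True)
        candidates.sort(key=lambda t: t[0], reverse=True)
        tree.remove_node(candidates[0][2])

    included = set(tree.nodes)
    selected: set[str] = set()
    total = 0.0
    for m in included:
        selected.update(meta_members[m])
        total += meta_weight[m]
    for a, b in tree.edges:
        key = (a, b) if (a, b) in path_nodes else (b, a)
        for v in path_nodes[key]:
            if v in meta_members:
                # connector path runs through another positive component
                if v not in included:
                    included.add(v)
                    selected.update(meta_members[v])
                    total += meta_weight[v]
            elif v not in selected:
                selected.add(v)
                total += w[v]

    if total < meta_weight[heaviest]:
        # Pathological pruning outcome; fall back to the single best component.
        selected = set(meta_members[heaviest])

    return _finalize(net, w, selected, meta_members)


def _finalize(
    net: InteractionNetwork,
    w: Mapping[str, float],
    selected: set[str],
    meta_members: Mapping[str, tuple[str, ...]],
) -> Module:
    """Absorb cost-free positive components adjacent to the selection."""
    changed = True
    while changed:
        changed = False
        for members in meta_members.values():
            if selected.issuperset(members):
                continue
            if any(
                nbr in selected for v in members for nbr in net.graph.neighbors(v)
            ) or any(v in selected for v in members):
                selected.update(members)
                changed = True
    sub = net.graph.subgraph(selected)
    assert nx.is_connected(sub), "heuristic produced a disconnected subgraph"
    return Module.from_nodes(net, selected)


def module_weight(net: InteractionNetwork, weights, module: Module) -> float:
    """Total signed node weight of a module under the given weight vector."""
    w = _weight_map(net, weights)
    return sum(w[v] for v in module.nodes)


def mwcs_exact(net: InteractionNetwork, weights, max_nodes: int = 16) -> Module:
    """Exact MWCS by enumeration of all connected induced subgraphs.

    Intended as a correctness oracle; refuses graphs above ``max_nodes``
    (default 16).  Ties are broken toward the lexicographically smallest
    node set.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network")
    if n > max_nodes:
        raise ValueError(f"exact solver limited to {max_nodes} nodes, got {n}")
    w = _weight_map(net, weights)
    nodes = net.nodes
    adj_mask = [0] * n
    for u, v in net.graph.edges:
        i, j = net.index[u], net.index[v]
        adj_mask[i] |= 1 << j
        adj_mask[j] |= 1 << i

    def connected(mask: int) -> bool:
        start = mask & -mask
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            m = frontier
            while m:
                bit = m & -m
                m ^= bit
                nxt |= adj_mask[bit.bit_length() - 1]
            frontier = nxt & mask & ~seen
            seen |= frontier
        return seen == mask

    best_mask, best_weight, best_set = 0, -np.inf, None
    for mask in range(1, 1 << n):
        if not connected(mask):
            continue
        total = 0.0
        m = mask
        members = []
        while m:
            bit = m & -m
            m ^= bit
            i = bit.bit_length() - 1
            total += w[nodes[i]]
            members.append(nodes[i])
        key = tuple(sorted(members))
        if total > best_weight + 1e-12 or (
            abs(total - best_weight) <= 1e-12 and (best_set is None or key < best_set)
        ):
            best_mask, best_weight, best_set = mask, total, key
    return Module.from_nodes(net, best_set)
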