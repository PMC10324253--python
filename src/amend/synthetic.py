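"""Synthetic benchmark instances with a planted active module.

The generator emulates the data regime the algorithm targets: a sparse,
scale-free-like protein-interaction network (preferential attachment, so
the degree distribution is heavy-tailed the way PPI networks are) into
which a small dense connected subgraph is planted and wired to the
background by a fixed, small number of bridge edges.  Genes in the planted
module carry extreme ECI values in the direction of interest; background
genes carry near-zero ECI noise.

Differential-expression effect sizes and p-values are emitted such that
recomputing the ECI from them reproduces each gene's target value exactly
(up to rounding noise), so the tables can be fed through the full text-file
pipeline and still produce the intended planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .eci import gene_stats_from_contrasts
from .network import InteractionNetwork

__all__ = ["SyntheticSpec", "generate_network", "generate_gene_stats", "generate_instance"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic instance.

    Defaults plant a 15-gene module with |ECI| in [0.7, 0.95] in the
    direction of interest inside a 500-node preferential-attachment
    background whose ECIs are centred on zero (scale 0.12, so |ECI| stays
    mostly below 0.3), attached by 2 bridge edges.
    """

    n_background: int = 500
    attachment: int = 2
    module_size: int = 15
    module_edge_prob: float = 0.35
    n_bridges: int = 2
    doi: int = -1
    planted_eci_range: tuple[float, float] = (0.7, 0.95)
    background_noise: float = 0.12
    seed: int = 1

    def __post_init__(self):
        if not 0 <= self.module_size < self.n_background:
            raise ValueError("module size must be smaller than the background")
        if not 0.0 <= self.module_edge_prob <= 1.0:
            raise ValueError("module edge probability must lie in [0, 1]")
        if self.doi not in (1, -1):
            raise ValueError("direction of interest must be +1 or -1")
        lo, hi = self.planted_eci_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("planted |ECI| range must lie in (0, 1)")


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(spec: SyntheticSpec) -> tuple[InteractionNetwork, tuple[str, ...]]:
    """Background network with a planted connected dense subgraph.

    Returns the network and the planted node labels.  The planted subgraph
    is an Erdos-Renyi draw at ``module_edge_prob`` forced connected by a
    random spanning chain, attached to the background by exactly
    ``n_bridges`` edges.
    """
    rng = np.random.default_rng(spec.seed)
    n_bg = spec.n_background
    g = nx.barabasi_albert_graph(n_bg, spec.attachment, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in range(n_bg)})
    planted = tuple(_gene_name(n_bg + j) for j in range(spec.module_size))
    if spec.module_size:
        # spanning chain over a random permutation guarantees connectivity
        order = rng.permutation(spec.module_size)
        for a, b in zip(order[:-1], order[1:]):
            g.add_edge(planted[a], planted[b])
        for i in range(spec.module_size):
            for j in range(i + 1, spec.module_size):
                if rng.uniform() < spec.module_edge_prob:
                    g.add_edge(planted[i], planted[j])
        anchors = rng.choice(spec.module_size, size=spec.n_bridges, replace=True)
        targets = rng.choice(n_bg, size=spec.n_bridges, replace=False)
        for a, t in zip(anchors, targets):
            g.add_edge(planted[a], _gene_name(t))
    return InteractionNetwork(g), planted


def _emit_contrast_rows(
    rng: np.random.Generator, target_eci: float
) -> tuple[float, float, float, float]:
    """(beta1, p1, beta2, p2) whose recomputed ECI equals ``target_eci``.

    With base effect b > 0, beta2 = lambda' * b where
    lambda' = target / (1 - max(p1, p2)); the min/max ratio then recovers
    |lambda'| and the p-discount restores the target exactly.
    """
    b = float(rng.uniform(1.0, 2.5))
    if target_eci == 0.0:
        return b, float(rng.uniform(0.2, 0.9)), 0.0, float(rng.uniform(0.2, 0.9))
    for _ in range(100):
        p1 = float(rng.uniform(0.0, 0.05))
        p2 = float(rng.uniform(0.0, 0.05))
        lam = target_eci / (1.0 - max(p1, p2))
        if abs(lam) <= 1.0:
            return b, p1, lam * b, p2
    # fall back to zero p-values: lambda' == target, always feasible
    return b, 0.0, target_eci * b, 0.0


def generate_gene_stats(
    spec: SyntheticSpec, nodes, planted
) -> pd.DataFrame:
    """Per-gene statistics table with planted extreme ECIs.

    Planted genes receive |ECI| drawn uniformly from the spec range with
    sign equal to the direction of interest; background genes receive
    ECIs from a clipped normal with scale ``background_noise`` (all zero
    when the noise scale is 0).  Significance flags mark |ECI| >= 0.5.
    """
    rng = np.random.default_rng(spec.seed + 1)
    planted = set(planted)
    rows = []
    for gene in sorted(str(n) for n in nodes):
        if gene in planted:
            lo, hi = spec.planted_eci_range
            target = spec.doi * float(rng.uniform(lo, hi))
        elif spec.background_noise == 0.0:
            target = 0.0
        else:
            target = float(
                np.clip(rng.normal(0.0, spec.background_noise), -0.9, 0.9)
            )
        beta1, p1, beta2, p2 = _emit_contrast_rows(rng, target)
        rows.append((gene, beta1, p1, beta2, p2, abs(target) >= 0.5))
    frame = pd.DataFrame(
        rows, columns=["gene_id", "beta1", "p1", "beta2", "p2", "significant"]
    )
    de1 = frame.rename(columns={"beta1": "log2fc", "p1": "pvalue"})[
        ["gene_id", "log2fc", "pvalue"]
    ]
    de2 = frame.rename(columns={"beta2": "log2fc", "p2": "pvalue"})[
        ["gene_id", "log2fc", "pvalue"]
    ]
    stats = gene_stats_from_contrasts(
        de1, de2, s=spec.doi,
        significant=frame.set_index("gene_id")["significant"],
    )
    return stats


def generate_instance(spec: SyntheticSpec):
    """Network, gene statistics, and planted labels for one instance."""
    net, planted = generate_network(spec)
    stats = generate_gene_stats(spec, net.nodes, planted)
    return net, stats, planted
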