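"""The iterative module-identification loop.

One run proceeds as follows.  Standardized ECI values are computed once on
the full gene set.  At iteration *i* the current network (initially the
whole input, restricted to genes with data and reduced to its largest
connected component) is diffused over with random walk with restart for
every restart value on a grid; propagation scores are shifted down by the
iteration's filtering-rate quantile; the Heinz-style heuristic extracts a
connected maximum-weight subgraph; and each candidate subgraph is scored by

    f(G) = mean standardized ECI of G  x  mean core-clustering coefficient of G

(topology measured inside G).  The best-scoring candidate becomes the next
iteration's network.  The filtering rate follows an exponential decay
schedule ``f(i) = eta0 * exp(-d (i - 1))`` whose decay ``d`` is calibrated
so a size simulation of the shrinking network lands at approximately the
requested final module size ``n``.  The loop stops when the node set stops
changing (or an iteration cap is hit); the final module is the
highest-scoring network seen across all iterations.

The starting filtering rate ``eta0`` may be fixed, or chosen by a seeded
global-best particle swarm maximizing the final module score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import quantile_shift, rwr
from .eci import seed_vector
from .mwcs import heinz_heuristic
from .network import (
    InteractionNetwork,
    Module,
    core_clustering_coefficient,
    core_normalized_transition,
    largest_connected_component,
)

__all__ = [
    "AmendConfig",
    "PSOSettings",
    "RunTrace",
    "TraceRecord",
    "filtering_rate",
    "simulate_sizes",
    "calibrate_decay",
    "score_network",
    "iterate_once",
    "run_amend",
    "optimize_eta0",
]

logger = logging.getLogger("amend")

DEFAULT_ALPHA_GRID = tuple(np.linspace(0.05, 0.95, 8))
DEFAULT_DECAY_GRID = tuple(np.geomspace(1e-3, 10.0, 60))


@dataclass(frozen=True)
class PSOSettings:
    """Global-best particle swarm hyperparameters for the eta0 search."""

    swarm_size: int = 10
    iterations: int = 20
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    bounds: tuple[float, float] = (0.1, 0.9)


@dataclass(frozen=True)
class AmendConfig:
    """Run configuration.

    Parameters
    ----------
    n:
        Approximate final module size the decay calibration aims for.
    s:
        Sign of the direction of interest: +1 seeks equivalently changed
        genes, -1 inversely changed genes.
    c:
        Relative seed weight for genes outside the direction of interest.
    alpha_grid:
        Restart probabilities tried at each iteration.
    eta0:
        Starting filtering rate in (0, 1), or None to optimize it by PSO.
    """

    n: int = 15
    s: int = -1
    c: float = 0.5
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID
    eta0: Optional[float] = 0.5
    decay_grid: Sequence[float] = DEFAULT_DECAY_GRID
    pso: PSOSettings = field(default_factory=PSOSettings)
    rwr_eps: float = 1e-10
    rwr_max_iter: int = 10_000
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("target module size n must be >= 1")
        if self.s not in (1, -1):
            raise ValueError("direction of interest s must be +1 or -1")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if self.eta0 is not None and not 0.0 < self.eta0 < 1.0:
            raise ValueError("eta0 must lie in (0, 1)")
        for a in self.alpha_grid:
            if not 0.0 < a < 1.0:
                raise ValueError("alpha grid values must lie in (0, 1)")


@dataclass(frozen=True)
class TraceRecord:
    """Per-iteration summary of the shrinking network."""

    iteration: int
    nodes: tuple[str, ...]
    n_edges: int
    score: float
    alpha: float
    filtering_rate: float
    mean_z: float
    mean_ccc: float


@dataclass
class RunTrace:
    """Full history of a run; the final module is the score argmax."""

    records: list[TraceRecord] = field(default_factory=list)
    eta0: float = float("nan")
    decay: float = float("nan")

    def best(self) -> TraceRecord:
        if not self.records:
            raise ValueError("empty trace")
        return max(self.records, key=lambda r: (r.score, -r.iteration))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "n_nodes": [len(r.nodes) for r in self.records],
                "n_edges": [r.n_edges for r in self.records],
                "score": [r.score for r in self.records],
                "alpha": [r.alpha for r in self.records],
                "filtering_rate": [r.filtering_rate for r in self.records],
                "mean_z": [r.mean_z for r in self.records],
                "mean_ccc": [r.mean_ccc for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# filtering-rate schedule


def filtering_rate(i: int, eta0: float, d: float) -> float:
    """Exponential-decay filtering rate ``eta0 * exp(-d (i - 1))``."""
    if i < 1:
        raise ValueError("iteration index starts at 1")
    if not 0.0 < eta0 < 1.0:
        raise ValueError("eta0 must lie in (0, 1)")
    if d < 0:
        raise ValueError("decay d must be non-negative")
    return eta0 * math.exp(-d * (i - 1))


def simulate_sizes(n0: int, eta0: float, d: float) -> list[int]:
    """Simulated network sizes under the schedule, until they stop changing.

    The filtering rate approximates the fraction of nodes dropped per
    iteration, so ``s_{i+1} = max(1, ceil(s_i * (1 - f(i))))``; the fixpoint
    size approximates the final module size for this (eta0, d).
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    sizes = [n0]
    i = 1
    while True:
        nxt = max(1, math.ceil(sizes[-1] * (1.0 - filtering_rate(i, eta0, d))))
        if nxt == sizes[-1]:
            return sizes
        sizes.append(nxt)
        i += 1


def calibrate_decay(
    n0: int, eta0: float, n: int, grid: Sequence[float] = DEFAULT_DECAY_GRID
) -> float:
    """Smallest grid decay whose simulated final size reaches at least ``n``.

    The simulated final size is non-decreasing in ``d``, so the smallest
    admissible grid value is well defined.

    Raises
    ------
    ValueError
        If no grid value reaches ``n`` (eta0 too large for the target size).
    """
    if not 1 <= n <= n0:
        raise ValueError("target size n must satisfy 1 <= n <= n0")
    for d in sorted(grid):
        if simulate_sizes(n0, eta0, d)[-1] >= n:
            return float(d)
    raise ValueError(
        f"no decay on the grid reaches final size {n} from n0={n0}, "
        f"eta0={eta0}; lower eta0 or extend the decay grid"
    )


# ---------------------------------------------------------------------------
# scoring and the inner iteration


def score_network(net: InteractionNetwork, z: pd.Series) -> float:
    """Network score: mean standardized ECI x mean core-clustering coefficient.

    Topology is measured within ``net`` itself, so the same node set scores
    differently inside different parent networks.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot score an empty network")
    mean_z = float(z.loc[list(net.nodes)].mean())
    mean_ccc = float(
        np.mean([core_clustering_coefficient(net, v) for v in net.nodes])
    )
    return mean_z * mean_ccc


def _module_summaries(net: InteractionNetwork, z: pd.Series) -> tuple[float, float]:
    mean_z = float(z.loc[list(net.nodes)].mean())
    mean_ccc = float(np.mean([core_clustering_coefficient(net, v) for v in net.nodes]))
    return mean_z, mean_ccc


def iterate_once(
    net: InteractionNetwork,
    stats: pd.DataFrame,
    k: float,
    alpha_grid: Sequence[float],
    config: AmendConfig,
) -> tuple[Module, float]:
    """One diffusion/extraction/scoring pass over the restart grid.

    For each restart value: build seeds from the original ECIs restricted to
    the current nodes, run the walk, shift by the ``k``-quantile, extract a
    connected subgraph, and score it.  Returns the best module and its
    restart value; ties go to the smaller restart value.  Restart values for
    which extraction fails (no positive weight) are skipped; if all fail a
    ValueError is raised.
    """
    if net.n_nodes < 2:
        raise ValueError("iteration requires at least 2 connected nodes")
    transition = core_normalized_transition(net)
    ecis = stats.loc[list(net.nodes), "eci"].to_numpy()
    seeds = seed_vector(ecis, s=config.s, c=config.c)
    z = stats["z"]
    best: tuple[float, float, Module] | None = None
    for alpha in sorted(alpha_grid):
        try:
            scores = rwr(
                transition, seeds, alpha, eps=config.rwr_eps,
                max_iter=config.rwr_max_iter,
            )
            shifted = quantile_shift(scores, k)
            module = heinz_heuristic(net, shifted)
        except ValueError:
            logger.debug("alpha=%.3f failed at k=%.4f; skipped", alpha, k)
            continue
        sub = net.subnetwork(module.nodes)
        score = score_network(sub, z)
        if best is None or score > best[0]:
            best = (score, alpha, module)
    if best is None:
        raise ValueError(f"subgraph extraction failed for every restart value at k={k}")
    score, alpha, module = best
    return replace(module, score=score, alpha=alpha, filtering_rate=k), alpha


def run_amend(
    net: InteractionNetwork,
    stats: pd.DataFrame,
    config: AmendConfig,
    eta0: Optional[float] = None,
) -> tuple[Module, RunTrace]:
    """Full iterative run with a fixed starting filtering rate.

    ``net`` is restricted to genes present in ``stats`` and reduced to its
    largest connected component before the loop starts.  Returns the
    highest-scoring module across iterations together with the full trace.
    """
    eta0 = config.eta0 if eta0 is None else eta0
    if eta0 is None:
        raise ValueError("eta0 not fixed; use optimize_eta0 for the PSO search")
    shared = [v for v in net.nodes if v in stats.index]
    if not shared:
        raise ValueError("no network node has gene statistics")
    if len(shared) < net.n_nodes:
        net = net.subnetwork(shared)
    if not net.is_connected():
        net = largest_connected_component(net)
    decay = calibrate_decay(net.n_nodes, eta0, config.n, config.decay_grid)
    # The size the schedule was calibrated to deliver: once the network has
    # shrunk to it, the filtering rate can no longer remove nodes in the
    # size simulation, so the run has reached its fixpoint ("no change in
    # network size").  Without this floor the extraction step sheds at
    # least the minimum-weight node every iteration and the trace would
    # collapse to a trivial extreme pair.
    target_size = simulate_sizes(net.n_nodes, eta0, decay)[-1]
    trace = RunTrace(eta0=eta0, decay=decay)
    current = net
    for i in range(1, config.max_iterations + 1):
        k = filtering_rate(i, eta0, decay)
        module, alpha = iterate_once(current, stats, k, config.alpha_grid, config)
        sub = net.subnetwork(module.nodes)
        mean_z, mean_ccc = _module_summaries(sub, stats["z"])
        trace.records.append(
            TraceRecord(
                iteration=i,
                nodes=module.nodes,
                n_edges=module.n_edges,
                score=module.score,
                alpha=alpha,
                filtering_rate=k,
                mean_z=mean_z,
                mean_ccc=mean_ccc,
            )
        )
        logger.info(
            "iteration %d: %d nodes, score %.4f, alpha %.3f, k %.4f",
            i, len(module.nodes), module.score, alpha, k,
        )
        if (
            module.nodes == current.nodes
            or len(module.nodes) < 2
            or len(module.nodes) <= target_size
        ):
            break
        current = net.subnetwork(module.nodes)
    best = trace.best()
    final = Module.from_nodes(
        net,
        best.nodes,
        score=best.score,
        iteration=best.iteration,
        alpha=best.alpha,
        filtering_rate=best.filtering_rate,
    )
    return final, trace


def optimize_eta0(
    net: InteractionNetwork,
    stats: pd.DataFrame,
    config: AmendConfig,
    seed: Optional[int] = None,
) -> tuple[float, Module, RunTrace]:
    """Choose the starting filtering rate by seeded global-best PSO.

    Each particle evaluation is one full :func:`run_amend`; the objective is
    the final module score.  Returns the best eta0, its module and trace.
    """
    pso = config.pso
    lo, hi = pso.bounds
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("PSO bounds must satisfy 0 < lo < hi < 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pos = rng.uniform(lo, hi, size=pso.swarm_size)
    vel = rng.uniform(-(hi - lo), hi - lo, size=pso.swarm_size) * 0.1
    cache: dict[float, tuple[Module, RunTrace]] = {}

    def evaluate(eta0: float) -> float:
        key = round(float(eta0), 12)
        if key not in cache:
            try:
                cache[key] = run_amend(net, stats, config, eta0=key)
            except ValueError:
                return -np.inf
        return cache[key][0].score

    pbest = pos.copy()
    pbest_val = np.array([evaluate(x) for x in pos])
    g = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g], pbest_val[g]
    for _ in range(pso.iterations):
        r1 = rng.uniform(size=pso.swarm_size)
        r2 = rng.uniform(size=pso.swarm_size)
        vel = (
            pso.inertia * vel
            + pso.cognitive * r1 * (pbest - pos)
            + pso.social * r2 * (gbest - pos)
        )
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([evaluate(x) for x in pos])
        improved = vals > pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmax(pbest_val))
        if pbest_val[g] > gbest_val:
            gbest, gbest_val = pbest[g], pbest_val[g]
    if not np.isfinite(gbest_val):
        raise ValueError("every PSO particle failed to produce a module")
    module, trace = cache[round(float(gbest), 12)]
    return float(gbest), module, trace
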