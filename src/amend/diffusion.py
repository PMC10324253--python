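"""Random walk with restart and the quantile shift to signed node weights.

The walk iterates ``P_i = (1 - alpha) A_N P_{i-1} + alpha P_0`` with a
column-stochastic transition matrix ``A_N`` and a unit-sum restart
distribution ``P_0`` until the max-norm change falls below ``eps``.  The
steady state measures each node's affinity to the seed genes.  Because the
matrix is column-stochastic and the seeds sum to one, total probability mass
is conserved at every step.

Propagation scores are all non-negative; the downstream maximum-weight
connected subgraph step needs both signs, so scores are shifted down by
their k-th sample quantile (linear interpolation between order statistics).
Roughly a fraction k of nodes end up negative, which is why k acts as the
per-iteration filtering rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["PropagationScores", "ShiftedWeights", "rwr", "rwr_exact", "quantile_shift"]

_COL_SUM_TOL = 1e-8


@dataclass(frozen=True)
class PropagationScores:
    """Steady-state affinity vector aligned to the network node order."""

    scores: np.ndarray
    alpha: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class ShiftedWeights:
    """Signed node weights after subtracting the k-th quantile."""

    weights: np.ndarray
    quantile: float


def _check_transition(transition: sp.spmatrix) -> sp.csr_matrix:
    t = sp.csr_matrix(transition)
    if t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    colsum = np.asarray(t.sum(axis=0)).ravel()
    if np.any(np.abs(colsum - 1.0) > _COL_SUM_TOL):
        raise ValueError("transition matrix is not column-stochastic")
    return t


def rwr(
    transition: sp.spmatrix,
    seeds: np.ndarray,
    alpha: float,
    eps: float = 1e-10,
    max_iter: int = 10_000,
) -> PropagationScores:
    """Power-iteration random walk with restart.

    Parameters
    ----------
    transition:
        Column-stochastic matrix aligned to the node order.
    seeds:
        Non-negative restart distribution summing to 1.
    alpha:
        Restart probability in (0, 1].  ``alpha = 1`` returns the seeds.
    eps:
        Max-norm convergence threshold on successive iterates.
    max_iter:
        Iteration cap; hitting it flags ``converged=False`` (not fatal).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("restart probability alpha must lie in (0, 1]")
    if eps <= 0:
        raise ValueError("eps must be positive")
    t = _check_transition(transition)
    p0 = np.asarray(seeds, dtype=float)
    if p0.shape != (t.shape[0],):
        raise ValueError("seed vector not aligned to transition matrix")
    if np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0, atol=1e-9):
        raise ValueError("seeds must be non-negative and sum to 1")
    if alpha == 1.0:
        return PropagationScores(p0.copy(), alpha, 0, True)
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - alpha) * (t @ p) + alpha * p0
        delta = np.max(np.abs(p_next - p))
        p = p_next
        if delta <= eps:
            return PropagationScores(p, alpha, it, True)
    return PropagationScores(p, alpha, max_iter, False)


def rwr_exact(transition: sp.spmatrix, seeds: np.ndarray, alpha: float) -> np.ndarray:
    """Direct linear solve ``P = alpha (I - (1 - alpha) A_N)^-1 P_0``.

    Reference solver for validation on small graphs; dense solve, so keep
    the network small.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("restart probability alpha must lie in (0, 1]")
    t = _check_transition(transition).toarray()
    n = t.shape[0]
    p0 = np.asarray(seeds, dtype=float)
    return alpha * np.linalg.solve(np.eye(n) - (1.0 - alpha) * t, p0)


def quantile_shift(scores, k: float) -> ShiftedWeights:
    """Shift propagation scores down by their k-th sample quantile.

    Uses the linear-interpolation sample quantile.  ``k = 0`` subtracts the
    minimum (all weights non-negative); for ``k`` in (0, 1) on non-constant
    scores both signs are present in the output.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError("quantile level k must lie in [0, 1]")
    p = scores.scores if isinstance(scores, PropagationScores) else np.asarray(scores, dtype=float)
    if p.size == 0:
        raise ValueError("empty score vector")
    q = float(np.quantile(p, k))
    return ShiftedWeights(p - q, k)
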