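"""Equivalent Change Index (ECI) and random-walk seed construction.

The ECI compares the log2 fold change of a gene between two
treatment-vs-control contrasts.  For gene *i* with effects (beta_i1, p_i1)
and (beta_i2, p_i2),

    eci_i = sign(beta_i1 * beta_i2)
            * min(|beta_i1|, |beta_i2|) / max(|beta_i1|, |beta_i2|)
            * (1 - max(p_i1, p_i2))

so that +1 means the gene moved identically in both contrasts (e.g. doubled
in both), -1 means it moved in exactly opposing ways (halved in one, doubled
in the other), and confidence is discounted by the worse of the two
p-values.  A zero effect in either contrast gives ECI 0 (sign(0) = 0
convention, which also avoids 0/0 in the ratio).

Downstream the package needs two derived quantities:

* a *standardized* ECI (z-score over the full gene set, sign-flipped so the
  direction of interest is positive) used in module scoring, and
* a *seed vector* for the random walk with restart, where genes whose ECI
  points away from the direction of interest keep a fraction ``c`` of the
  weight an equally extreme gene in the direction of interest would get.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_eci",
    "standardize_eci",
    "seed_vector",
    "gene_stats_from_contrasts",
]


def compute_eci(beta1: float, p1: float, beta2: float, p2: float) -> float:
    """ECI for one gene from two (log2 fold change, p-value) pairs.

    Returns a value in [-1, 1]; 0 whenever either effect is exactly 0 or the
    worse p-value is 1.

    Raises
    ------
    ValueError
        If either p-value is outside [0, 1] or any input is non-finite.
    """
    for p in (p1, p2):
        if not np.isfinite(p) or not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    if not (np.isfinite(beta1) and np.isfinite(beta2)):
        raise ValueError("log2 fold changes must be finite")
    if beta1 == 0.0 or beta2 == 0.0:
        return 0.0
    a1, a2 = abs(beta1), abs(beta2)
    ratio = min(a1, a2) / max(a1, a2)
    return float(np.sign(beta1 * beta2)) * ratio * (1.0 - max(p1, p2))


def compute_eci_vector(
    beta1: np.ndarray, p1: np.ndarray, beta2: np.ndarray, p2: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`compute_eci` over aligned arrays."""
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | ~np.isfinite(p1)) or np.any(
        (p2 < 0) | (p2 > 1) | ~np.isfinite(p2)
    ):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(~np.isfinite(beta1)) or np.any(~np.isfinite(beta2)):
        raise ValueError("log2 fold changes must be finite")
    a1, a2 = np.abs(beta1), np.abs(beta2)
    hi = np.maximum(a1, a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hi > 0, np.minimum(a1, a2) / np.where(hi > 0, hi, 1.0), 0.0)
    out = np.sign(beta1 * beta2) * ratio * (1.0 - np.maximum(p1, p2))
    out[(beta1 == 0) | (beta2 == 0)] = 0.0
    return out


def standardize_eci(ecis: Sequence[float], s: int = 1) -> np.ndarray:
    """Z-score the ECI vector over the full gene set, then flip by ``s``.

    ``s`` is the sign of the direction of interest (+1 equivalent change,
    -1 inverse change); after the flip, genes in the direction of interest
    carry positive standardized values.  Sample standard deviation (ddof=1)
    is used.

    Raises
    ------
    ValueError
        Fewer than 2 values, degenerate (zero) variance, or ``s`` not +/-1.
    """
    if s not in (1, -1):
        raise ValueError("direction of interest s must be +1 or -1")
    e = np.asarray(ecis, dtype=float)
    if e.size < 2:
        raise ValueError("standardization needs at least 2 genes")
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("ECI vector has zero variance; cannot standardize")
    return s * (e - e.mean()) / sd


def seed_vector(ecis: Sequence[float], s: int = 1, c: float = 0.5) -> np.ndarray:
    """Restart distribution for the random walk from ECI values.

    Weight is proportional to |eci| for genes whose ECI lies in the
    direction of interest (``s * eci > 0``) and ``c * |eci|`` otherwise,
    normalized to sum to 1.  With ``s = -1`` and ``c = 0.5`` a gene with
    ECI ``+x`` gets exactly half the weight of a gene with ECI ``-x``.

    Raises
    ------
    ValueError
        All-zero ECI vector (no seed mass), ``c`` outside [0, 1], or bad s.
    """
    if s not in (1, -1):
        raise ValueError("direction of interest s must be +1 or -1")
    if not 0.0 <= c <= 1.0:
        raise ValueError("off-direction weight c must lie in [0, 1]")
    e = np.asarray(ecis, dtype=float)
    in_doi = (s * e) > 0
    w = np.abs(e) * np.where(in_doi, 1.0, c)
    total = w.sum()
    if total <= 0:
        raise ValueError("all seed weights are zero; no valid restart vector")
    return w / total


def gene_stats_from_contrasts(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    s: int = 1,
    significant: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Merge two differential-expression tables into a per-gene ECI table.

    Each input frame must have columns ``gene_id``, ``log2fc``, ``pvalue``
    (or be indexed by gene with those value columns).  Genes are matched by
    exact identifier string; only the intersection is kept.  Returns a frame
    indexed by ``gene_id`` with columns ``beta1 p1 beta2 p2 eci z`` and
    optionally ``significant``.
    """

    def _normalize(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        if "gene_id" in df.columns:
            df["gene_id"] = df["gene_id"].astype(str)
            df = df.set_index("gene_id")
        else:
            df.index = df.index.astype(str)
        missing = {"log2fc", "pvalue"} - set(df.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        return df[["log2fc", "pvalue"]]

    d1, d2 = _normalize(de1), _normalize(de2)
    genes = d1.index.intersection(d2.index).sort_values()
    if genes.empty:
        raise ValueError("no genes shared between the two contrasts")
    stats = pd.DataFrame(
        {
            "beta1": d1.loc[genes, "log2fc"].to_numpy(dtype=float),
            "p1": d1.loc[genes, "pvalue"].to_numpy(dtype=float),
            "beta2": d2.loc[genes, "log2fc"].to_numpy(dtype=float),
            "p2": d2.loc[genes, "pvalue"].to_numpy(dtype=float),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    stats["eci"] = compute_eci_vector(
        stats["beta1"], stats["p1"], stats["beta2"], stats["p2"]
    )
    stats["z"] = standardize_eci(stats["eci"].to_numpy(), s=s)
    if significant is not None:
        sig = significant.copy()
        sig.index = sig.index.astype(str)
        stats["significant"] = sig.reindex(genes).astype("boolean")
    return stats
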