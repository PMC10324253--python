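"""Module quality statistics, enrichment analysis, and consistency indices.

Covers the statistics used to judge an identified module:

* descriptive summaries (size, edge density, median ECI, proportion of
  genes with a significant ECI where significance flags are supplied);
* overrepresentation analysis (ORA): upper-tail hypergeometric test of the
  overlap between a module and each gene set, Benjamini-Hochberg adjusted
  across sets, with all network genes as the background universe;
* the empirical-to-hypergeometric ratio (EHR) and its per-module variant
  (mEHR): the fraction of significantly enriched gene sets that survive a
  permutation null built by re-running the whole pipeline on data with gene
  statistics shuffled across genes;
* Jaccard and Nested indices between modules, with a bootstrap p-value
  obtained by resampling each module's binary membership vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import InteractionNetwork, Module

__all__ = [
    "GeneSetCollection",
    "module_stats",
    "hypergeom_ora",
    "enrichment_scores",
    "ehr",
    "jaccard",
    "nested",
    "bootstrap_index_pvalue",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        uni = frozenset(str(g) for g in universe)
        if not uni:
            raise ValueError("empty background universe")
        trimmed = {}
        for name, members in sets.items():
            inter = frozenset(str(g) for g in members) & uni
            if inter:
                trimmed[name] = inter
        return cls(trimmed, uni)


def module_stats(
    module: Module, stats: pd.DataFrame
) -> dict[str, float | int | None]:
    """Descriptive summary of a module against the gene statistics table.

    Returns node count, edge count, edge density ``2E / (n (n - 1))``
    (0 for a single node by convention), median ECI, and the proportion of
    module genes flagged significant — ``None`` when no flags are present.
    """
    genes = list(module.nodes)
    missing = [g for g in genes if g not in stats.index]
    if missing:
        raise KeyError(f"module genes missing from stats: {missing[:5]}")
    n = module.n_nodes
    density = 0.0 if n < 2 else 2.0 * module.n_edges / (n * (n - 1))
    out: dict[str, float | int | None] = {
        "n_nodes": n,
        "n_edges": module.n_edges,
        "edge_density": density,
        "median_eci": float(stats.loc[genes, "eci"].median()),
    }
    if "significant" in stats.columns and stats["significant"].notna().any():
        flags = stats.loc[genes, "significant"].astype(bool)
        out["proportion_significant"] = float(flags.mean())
    else:
        out["proportion_significant"] = None
    return out


def hypergeom_ora(
    module_genes: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation test per gene set.

    For a universe of ``N`` genes containing ``K`` set members, a module of
    size ``n`` overlapping the set in ``x`` genes has
    ``p = P(X >= x)`` for ``X ~ Hypergeom(N, K, n)``.  P-values are
    Benjamini-Hochberg adjusted across sets; ``significant`` marks adjusted
    p <= ``alpha``.  Returns a frame indexed by set name, sorted by p-value.
    """
    if not collection.universe:
        raise ValueError("empty background universe")
    module_set = frozenset(str(g) for g in module_genes) & collection.universe
    n_universe = len(collection.universe)
    n_module = len(module_set)
    names, overlaps, pvals = [], [], []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        x = len(module_set & members)
        # P(X >= x) = sf(x - 1)
        p = float(sps.hypergeom.sf(x - 1, n_universe, len(members), n_module))
        names.append(name)
        overlaps.append(x)
        pvals.append(min(1.0, p))
    if not names:
        return pd.DataFrame(
            columns=["overlap", "set_size", "pvalue", "adjusted_pvalue", "significant"]
        )
    adj = multipletests(pvals, method="fdr_bh")[1]
    frame = pd.DataFrame(
        {
            "overlap": overlaps,
            "set_size": [len(collection.sets[n]) for n in names],
            "pvalue": pvals,
            "adjusted_pvalue": adj,
            "significant": adj <= alpha,
        },
        index=pd.Index(names, name="gene_set"),
    )
    return frame.sort_values(["pvalue", "gene_set"], kind="stable")


def enrichment_scores(
    modules: Sequence[Iterable[str]], collection: GeneSetCollection
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-set enrichment score across modules: max of -log10(raw p).

    Also returns the per-set minimum BH-adjusted p across modules (used for
    the hypergeometric arm of the EHR definition).
    """
    if not modules:
        raise ValueError("need at least one module")
    names = sorted(collection.sets)
    score = pd.Series(0.0, index=pd.Index(names, name="gene_set"))
    min_adj = pd.Series(1.0, index=score.index)
    for module_genes in modules:
        ora = hypergeom_ora(module_genes, collection)
        with np.errstate(divide="ignore"):
            s = -np.log10(ora["pvalue"].reindex(names).to_numpy())
        score = np.maximum(score, pd.Series(s, index=score.index))
        min_adj = np.minimum(min_adj, ora["adjusted_pvalue"].reindex(names))
    return score, pd.DataFrame({"score": score, "min_adjusted_pvalue": min_adj})


def ehr(
    original_modules: Sequence[Iterable[str]],
    permuted_runner: Callable[[int], Sequence[Iterable[str]]],
    collection: GeneSetCollection,
    n_permutations: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Empirical-to-hypergeometric ratio with a permutation null.

    ``permuted_runner(b)`` must re-run the module-identification method on
    data whose gene statistics were permuted across genes (the b-th
    permutation) and return the resulting modules.  A set is *empirically
    validated* (EV) when its empirical p (share of null enrichment scores
    >= the observed score, ties counting toward the null) is <= ``alpha``
    AND its minimum BH-adjusted hypergeometric p across original modules is
    <= ``alpha``.  EHR is the EV fraction among sets significant for any
    original module; mEHR is the same fraction per original module.

    Returns a dict with keys ``ehr`` (None when no set is significant),
    ``mehr`` (list per module), ``empirical_pvalues``, ``table``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    obs_score, obs_table = enrichment_scores(original_modules, collection)
    names = obs_score.index
    null = np.zeros((n_permutations, len(names)))
    for b in range(n_permutations):
        perm_modules = permuted_runner(b)
        if perm_modules:
            null[b] = enrichment_scores(perm_modules, collection)[0].to_numpy()
    emp_p = pd.Series(
        (null >= obs_score.to_numpy()[None, :]).mean(axis=0), index=names
    )
    ev = (emp_p <= alpha) & (obs_table["min_adjusted_pvalue"] <= alpha)
    significant_any = obs_table["min_adjusted_pvalue"] <= alpha
    overall = (
        float((ev & significant_any).sum() / significant_any.sum())
        if significant_any.any()
        else None
    )
    mehr = []
    for module_genes in original_modules:
        ora = hypergeom_ora(module_genes, collection, alpha=alpha)
        sig = ora.index[ora["significant"]]
        if len(sig) == 0:
            mehr.append(None)
        else:
            mehr.append(float(ev.loc[sig].mean()))
    table = pd.DataFrame(
        {
            "score": obs_score,
            "min_adjusted_pvalue": obs_table["min_adjusted_pvalue"],
            "empirical_pvalue": emp_p,
            "empirically_validated": ev,
            "significant": significant_any,
        }
    )
    return {
        "ehr": overall,
        "mehr": mehr,
        "empirical_pvalues": emp_p,
        "table": table,
    }


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|A n B| / |A u B|."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("Jaccard index requires non-empty sets")
    return len(sa & sb) / len(sa | sb)


def nested(a: Iterable[str], b: Iterable[str]) -> float:
    """|A n B| / min(|A|, |B|) — how far one set is nested in the other."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("Nested index requires non-empty sets")
    return len(sa & sb) / min(len(sa), len(sb))


def bootstrap_index_pvalue(
    a: Iterable[str],
    b: Iterable[str],
    universe: Iterable[str],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> dict[str, float]:
    """Bootstrap p-values for the Jaccard and Nested indices of two modules.

    Each module is a binary membership vector over the universe; each
    bootstrap replicate resamples both vectors' elements with replacement
    (destroying positional alignment, preserving module sizes in
    expectation) and recomputes both indices.  The p-value is the share of
    replicates whose index is >= the observed one.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    universe = sorted(set(str(g) for g in universe))
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    va = np.array([g in set(a) for g in universe], dtype=np.int8)
    vb = np.array([g in set(b) for g in universe], dtype=np.int8)
    obs_j = jaccard(a, b)
    obs_n = nested(a, b)
    rng = np.random.default_rng(seed)
    ge_j = 0
    ge_n = 0
    for _ in range(n_boot):
        ra = rng.choice(va, size=n, replace=True)
        rb = rng.choice(vb, size=n, replace=True)
        inter = int(np.sum(ra & rb))
        union = int(np.sum(ra | rb))
        small = min(int(ra.sum()), int(rb.sum()))
        bj = inter / union if union else 0.0
        bn = inter / small if small else 0.0
        ge_j += bj >= obs_j
        ge_n += bn >= obs_n
    return {
        "jaccard": obs_j,
        "nested": obs_n,
        "jaccard_pvalue": ge_j / n_boot,
        "nested_pvalue": ge_n / n_boot,
    }
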