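# amend

Active module identification from two differential-expression contrasts and
a protein–protein interaction (PPI) network.

Given per-gene results from two treatment-vs-control experiments, the
package finds a single **connected** subnetwork whose genes are strongly
*equivalently* or *inversely* regulated between the two contrasts — for
example, genes that move in opposite directions between a knockout and an
overexpression of the same transporter, or in the same direction under two
drugs with a shared mechanism.

## The method

Per-gene signal is the **Equivalent Change Index (ECI)**. For gene *i* with
log2 fold changes β<sub>i1</sub>, β<sub>i2</sub> and p-values
p<sub>i1</sub>, p<sub>i2</sub>:

```
λ_i = sign(β_i1 β_i2) · min(|β_i1|,|β_i2|)/max(|β_i1|,|β_i2|) · (1 − max(p_i1, p_i2))
```

λ ∈ [−1, 1]: +1 means identical change in both contrasts, −1 exactly
opposing change, and the worse p-value discounts confidence.

The search then iterates four steps on a shrinking network:

1. **Seed construction** — restart weights ∝ |λ|, with genes pointing away
   from the chosen direction of interest down-weighted by a factor
   c ∈ [0, 1] (default 0.5).
2. **Random walk with restart** — `P_i = (1−α) A_N P_{i−1} + α P_0`, where
   `A_N` is column-normalized by node *coreness* (k-core number) rather than
   degree, attenuating the degree bias of PPI networks. The restart α is
   chosen per iteration by a grid search.
3. **Quantile shift + maximum-weight connected subgraph** — propagation
   scores are shifted down by their k-th quantile so both signs are present,
   and a Heinz-style spanning-tree heuristic extracts a connected subgraph
   maximizing total signed weight. k follows an exponential decay schedule
   `f(i) = η₀ e^{−d(i−1)}` whose decay d is calibrated so the simulated
   shrinkage lands at a user-chosen approximate module size n.
4. **Scoring** — each candidate is scored by
   `f(G) = mean standardized ECI × mean core-clustering coefficient`
   (the MCODE neighborhood-density statistic); the best-scoring network seen
   across iterations is the final module.

The starting filtering rate η₀ may be fixed or optimized by a seeded
particle swarm. Evaluation utilities cover hypergeometric
overrepresentation analysis (ORA) with Benjamini–Hochberg correction, the
permutation-based empirical-to-hypergeometric ratio (EHR/mEHR), and
Jaccard/Nested module-consistency indices with bootstrap significance.

## Worked example

Generate a synthetic benchmark — a 500-node scale-free background with a
planted 15-gene module whose ECIs lie in [−0.95, −0.7] against near-zero
background noise — and recover the module:

```sh
$ amend simulate --seed 1 --out demo/data
instance: 515 nodes, 1047 edges, 15 planted genes; written to demo/data

$ amend run --network demo/data/network.tsv --de1 demo/data/de1.tsv \
    --de2 demo/data/de2.tsv --doi neg --n 15 --eta0 0.5 --seed 1 --out demo/run
module: 15 nodes, 49 edges, score 3.2280 (iteration 5, alpha 0.821); outputs in demo/run
```

The run shrinks the network over five iterations (515 → 261 → 149 → 77 →
34 → 15 nodes) and returns the 15-node candidate, which here is exactly the
planted gene set (Jaccard 1.0 against `demo/data/planted_nodes.txt`). The
score 3.2280 is the product of the module's mean standardized ECI (4.40 —
its genes are ~4.4 standard deviations more inversely-changed than an
average gene) and its mean core-clustering coefficient (0.73 — a densely
interconnected neighborhood). `demo/run/` contains the module node/edge
tables, a GraphML export, and `run_report.json` with the full per-iteration
trace.

Real data enter the same way: a STRING links file (`combined_score ≥ 800`
kept by default), two DE tables with columns `gene_id, log2fc, pvalue`, and
optionally a GMT pathway collection for `amend eval` / `amend consistency`.

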