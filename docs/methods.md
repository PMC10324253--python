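# Methods

This note records the model implemented by the package, the defaults and
why they were chosen, the numerical conventions that affect results, and
the known limits of what the test suite demonstrates.

## Signal model: the Equivalent Change Index

The ECI compares effect sizes between two treatment-vs-control contrasts:

    λ_i = sign(β_i1 β_i2) · min(|β_i1|,|β_i2|) / max(|β_i1|,|β_i2|) · (1 − max(p_i1, p_i2))

It is symmetric in the contrasts, bounded in [−1, 1], and |λ| is
non-increasing both in the worse p-value and in the disparity of the two
effects. Two conventions are ours, fixed because the quantity is undefined
otherwise: a zero effect in either contrast gives λ = 0 (sign(0) = 0, which
also avoids 0/0), and genes missing from either contrast are dropped at the
join. ECI significance flags are accepted as an optional input column;
the package does not compute them (the proportion-significant module
statistic is reported as unavailable when flags are absent).

Standardized values z = s·(λ − mean)/sd use the sample standard deviation
(ddof = 1) over the full gene set, computed once before the iteration and
flipped by the direction-of-interest sign s *after* standardizing (the two
orders differ only in the sign of an affine map; one was fixed for
reproducibility). Seed vectors weight a gene by |λ| when s·λ > 0 and by
c·|λ| otherwise, normalized to unit sum; c defaults to 0.5, meaning a gene
pointing the wrong way gets exactly half the restart mass of an equally
extreme gene pointing the right way.

## Diffusion

The transition matrix is column-normalized by k-core number: entry (i, j)
is k_i / Σ_l k_l over the neighbors l of j. Coreness correlates with degree
but saturates on star-like hubs, which attenuates the ascertainment-driven
degree bias of PPI networks; on k-regular graphs the scheme reduces exactly
to degree normalization (a closed-form check in the suite). The walk
`P_i = (1−α) A_N P_{i−1} + α P_0` is solved by power iteration with
convergence threshold 1e−10 in max norm and an iteration cap of 10,000
(values chosen so that the iterate agrees with the direct resolvent solve
to better than 1e−8 for any α ≥ 0.05; the cap is never reached in
practice). A dense direct solve is provided for validation only.

Shifted weights are p′ = p − Q_k(P) with the linear-interpolation sample
quantile. The quantile convention matters: alternatives differ in how many
nodes end up exactly at zero, so it is pinned for cross-run
reproducibility.

## Subgraph extraction

The maximum-weight connected subgraph step is a deterministic spanning-tree
heuristic: (1) contract each connected component of positive-weight nodes
into a meta-node carrying the component's total weight; (2) join meta-nodes
by cheapest connector paths, where entering a negative node costs |w| and
zero-weight nodes are free (Dijkstra with node costs); (3) take a minimum
spanning tree of the meta-graph under edge cost (path cost) − (incident
meta-node weights); (4) iteratively prune tree leaves whose connector costs
more than the weight they bring, worst offender first; (5) expand back to
original nodes and absorb any positive component reachable at zero cost.
All tie-breaks are by ascending node identifier, so the output is a
deterministic function of the input. If pruning leaves less weight than the
heaviest single positive component, that component is returned instead, so
the result is never worse than trivially achievable. On a randomized suite
of signed graphs small enough for exhaustive enumeration, the heuristic
attains ≥ 0.8 of the exact optimum on every instance and is optimal on
~98% of them (asserted at a conservative 0.6 floor).

## The outer loop and its stopping rule

The filtering rate follows f(i) = η₀·e^{−d(i−1)}. Given η₀ and the target
size n, the decay d is the smallest value on a geometric grid (60 points in
[1e−3, 10]) whose simulated size sequence — s₁ = |V|,
s_{i+1} = max(1, ceil(s_i(1−f(i)))), stopped at the first fixpoint — ends
at ≥ n. Ceil rounding with a floor of 1 is our convention; calibration
depends on it, and the monotonicity of the final size in d (property-tested)
is what makes "smallest admissible d" well defined.

The loop stops when the node set no longer changes, when fewer than two
nodes remain, **or when the module size reaches the calibrated schedule's
simulated fixpoint size**. The last condition is the operative one and a
deliberate design choice: for any k > 0 the quantile shift makes at least
the minimum-score node strictly negative, so the extraction step sheds at
least one node per iteration and a purely change-based stop would let the
trace collapse to a 2-node clique of the two most extreme connected genes —
which, having core-clustering coefficient 1 and maximal mean z, would then
dominate the score argmax and make the returned module trivial. Stopping at
the schedule's own fixpoint implements "no change in network size" in the
sense the size simulation defines it and keeps the final module near the
requested size n. The iteration cap is 100.

The restart grid defaults to 8 evenly spaced values in [0.05, 0.95]; per
iteration the grid value with the best-scoring extracted subgraph wins,
ties to the smaller α. Seeds are re-extracted each iteration from the
*original* ECIs restricted to the surviving nodes and renormalized —
propagated scores are never fed back as seeds, keeping iterations
comparable. Module scores use the core-clustering coefficient (edge density
of the densest k-core of a node's closed neighborhood, node included —
the MCODE convention) computed within the module's induced subgraph.

η₀ is either fixed (default 0.5) or maximized by a global-best particle
swarm over [0.1, 0.9]: swarm 10, 20 iterations, inertia 0.7, cognitive and
social coefficients 1.5, fully seeded; each evaluation is a complete run.
These are standard PSO settings; the objective is one-dimensional and
smooth enough that modest swarms suffice, and evaluations are cached per
η₀.

## Evaluation statistics

ORA uses the upper-tail hypergeometric probability P(X ≥ x) with all
network genes as the universe and Benjamini–Hochberg adjustment across
gene sets (significance at adjusted p ≤ 0.05). The EHR permutation null
shuffles the per-gene statistics uniformly across network genes and re-runs
the entire pipeline per permutation; a set's empirical p is the share of
null enrichment scores (max over modules of −log10 raw p) at or above the
observed score — ties count toward the null, the conservative direction.
A set is empirically validated when both its empirical p and its minimum
adjusted hypergeometric p are ≤ 0.05; EHR is the validated fraction among
significant sets and is reported as unavailable when nothing is
significant. The default of 50 permutations is a desk-scale setting;
production analyses should use an order of magnitude more.

Consistency between two modules is measured by the Jaccard and Nested
indices; significance comes from resampling each module's binary membership
vector over the network with replacement (destroying positional alignment
while preserving expected module size) and counting replicates with an
index at or above the observed value.

## Synthetic benchmark

The generator plants a connected module of m = 15 genes (intra-module edge
probability 0.35 over a guaranteed spanning chain, attached to the
background by exactly 2 bridge edges) into a 500-node preferential-
attachment background (attachment 2). Planted genes carry |ECI| uniform in
[0.7, 0.95] in the direction of interest; background ECIs are normal with
scale 0.12, clipped, so almost all stay below 0.3 in magnitude. Effect
sizes and p-values are emitted so that recomputing the ECI from the written
DE tables reproduces each target exactly: β₁ = b, β₂ = λ′b with
λ′ = λ/(1 − max p), which the min/max ratio and p-discount invert.
Two bridges make recovery non-trivial (diffusion must not leak the module
away) but possible (the module is a coherent dense region). The generator
emulates degree heterogeneity and planted signal only: it has no
co-expression covariance, no sample-level noise, and its background is
sparser than a high-confidence STRING network, so passing recovery tests
demonstrates algorithmic correctness under the stated conditions, not
field performance on real transcriptomes.

## Problem sizes used in the checks

The automated checks run the full pipeline on the 500-node default instance
(recovery, reproducibility), a 150-node instance for engine unit tests, a
250-node instance with 10 permutations for the EHR computation, 100 random
graphs ≤ 50 nodes for walk/solver agreement, and 200 random signed graphs
≤ 14 nodes for the heuristic-vs-oracle comparison. These sizes were chosen
so the whole suite completes in about a minute while still exercising every
code path at non-toy scale.

## Known limitations

* The subgraph heuristic has no approximation guarantee; the 0.6 floor is
  empirical on the tested graph family.
* The schedule's size simulation treats the filtering rate as the exact
  per-iteration shrink fraction; real shrinkage is faster on sparse
  networks (scattered positives are unreachable and get dropped), so the
  returned module can land below n before the schedule predicts it.
* Edge confidences are used only for input thresholding; the walk is
  unweighted (a weighted adjacency is available behind a flag in the
  network container but is not the default).
* ECI significance testing (bootstrap over samples) is out of scope; flags
  must be supplied if the proportion-significant statistic is wanted.
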