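# Methods

## Model and procedure

All engines operate on simple undirected graphs `G = (V, E)` (self-loops
dropped on input, duplicate edges collapsed; node identifiers are opaque
strings). Propagation state is a labeling `c : V → labels`, initialised
with each node's own identifier, so labels are unique at sweep 0.

One **asynchronous sweep** visits nodes in some order; each node computes
the per-label support of its neighbours — neighbour counts on unweighted
graphs, sums of edge weights `w_ij` on weighted ones — and adopts the
plurality label immediately, so nodes later in the sweep see the update.
Isolated nodes are skipped (a plurality over an empty neighbourhood is
undefined) and end as singleton communities. At the end, nodes sharing a
label become one community; community ids are renumbered canonically
(consecutive integers ordered by each community's smallest member) so
partitions compare with `==` independently of the labels propagation
happened to converge on.

The three engines differ in visit order and tie-breaking:

| engine  | visit order                            | plurality tie-break                  | randomness |
|---------|----------------------------------------|--------------------------------------|------------|
| lpa     | fresh uniform shuffle every sweep      | uniform among tied labels            | seeded RNG |
| kblpa   | fixed: k-shell `Ks` desc, node id asc  | uniform among tied labels            | seeded RNG |
| niblpa  | fixed: influence `NI` desc, node id asc| max label influence `LI`, then smallest label id | none |

`Ks(i)` is the standard shell index from k-core peeling on the whole
(possibly disconnected) graph; degree-0 nodes get shell 0. Node influence
is `NI(i) = Ks(i) + α·Σ_{j∈N(i)} Ks(j)/d(j)`; label influence of label
`l` at node `i` is `LI(l) = Σ_{j∈N(i), c_j=l} NI(j)/d(j)`. NI is computed
once during initialisation and never refreshed during sweeps. On weighted
graphs, weights enter only the neighbour-label support; `Ks`, `d`, `NI`
and `LI` always use the unweighted structure, since the influence
quantities are defined on topology alone (a logged notice records this
when a weighted graph is passed to the deterministic engine).

The LI rule is applied strictly: whenever `|l_max| > 1` the LI-argmax
label is adopted even if the node's current label is also in `l_max`; the
iteration cap bounds any cycling this could induce (none has been observed
on the benchmark families).

## Convergence and iteration counting

After each mutating sweep a **read-only full pass** decides convergence:

* stochastic engines — stable iff every non-isolated node's current label
  is in its plurality set `l_max` (some admissible tie-break would keep it);
* deterministic engine — stable iff every node's label equals the exact
  choice its update rule would make.

`iterations` counts mutating sweeps only; the confirming pass is free.
Under this rule the six-node worked example converges with
`iterations = 1`, and an edgeless graph converges after its first (no-op)
sweep. If `max_iter` (default 100) is reached without stability the
partition is still returned with `converged = False` and a warning; the
CLI then exits non-zero unless `--allow-nonconverged` is given.

## Parameters

* `α ∈ [0, 1]` (default 1.0) — weight of the neighbourhood term in NI.
  `α = 0` reduces NI to the bare shell index (the kblpa ordering up to
  degree effects); larger α separates nodes sharing a shell by how
  core-connected their neighbourhoods are. The best α is
  network-dependent, so the CLI exposes `--alpha` and the bench command a
  grid; 1.0 is the package-wide default and the value used in all shipped
  benchmarks. Values outside [0, 1] are accepted with a logged warning.
* `max_iter` (default 100) — sweep cap; benchmark families converge in a
  handful of sweeps.
* `seed` — controls the stochastic engines only. Benchmark repeats derive
  per-run seeds as `(master·1000003 + i) mod (2³¹ − 1)`, making repeated
  protocols reproducible and parallelisable.

## Tie-break conventions

Every "by node id" rule uses one total order: identifiers that parse as
integers sort numerically (before all others), the rest lexicographically.
Exact LI ties break to the smallest label under this order — a choice the
method itself leaves open; smallest-id is deterministic and independent of
dict iteration order. Visit-order ties (equal NI or equal Ks) break the
same way.

## Metrics

* **Modularity** `Q = Σ_c [L_c/m − (D_c/2m)²]` (equivalently the ordered
  pair form `(1/2m)Σ_ij (A_ij − d_i d_j/2m) δ(c_i,c_j)`), unweighted
  graphs only; undefined (raises) when `m = 0`.
* **Pair F-measure** — precision/recall over unordered same-cluster pairs,
  computed from the contingency table. Conventions: no retrieved pairs →
  precision 0 → F 0; neither partition has pairs → F 1.
* **NMI** — sum-normalised mutual information `2I/(H(X)+H(Y))` from the
  contingency table, natural logs, `0·log 0 = 0`, clamped to [0, 1]
  against float spill. Two one-community partitions (both entropies zero)
  are identical, so NMI = 1 by convention; one trivial vs one non-trivial
  partition gives 0 (the natural limit). This normalisation equals
  scikit-learn's arithmetic-mean NMI, which the tests use as an
  independent oracle at 1e-12.

## Synthetic benchmarks

`clique_ring(n, m)` builds `m` complete graphs `K_n` (nodes `c{q}_{r}`)
and joins clique `q`'s last node to clique `q+1 mod m`'s first node,
giving exactly `N = mn` nodes and `M = mn(n−1)/2 + m` edges with the
cliques as ground truth. Any single-bridge-per-adjacent-pair wiring yields
these counts; the last-to-first convention is fixed so outputs are
reproducible byte-for-byte. The shipped configurations are (n, m) =
(5, 5), (5, 10), (10, 10) and (5, 30).

`planted_partition(n, k, p_in, p_out, seed)` splits `n` nodes into `k`
communities whose sizes differ by at most one and draws each
within-community pair with probability `p_in` and each between-community
pair with `p_out`, independently under a seeded RNG. It emulates the
community signal-to-noise axis (recovery degrades as `p_out → p_in`) but
**not** the power-law degree and community-size heterogeneity of
LFR-style benchmarks — passing the mixing-degradation test here says
nothing about heavy-tailed networks. Real networks additionally have
overlapping modules, hubs and degree assortativity that neither generator
produces, so benchmark-perfect scores bound best-case, not typical,
behaviour.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at the benchmark sizes
above (25–150 nodes) with 100 repeats for stochastic engines, and use
brute-force oracles on graphs of ≤ 12–14 nodes — sizes at which exhaustive
enumeration is exact and the whole suite completes in seconds. Floating
point enters only through NI/LI sums and the metrics; plurality supports
are exact integers on unweighted graphs, and LI comparisons use exact
float equality deliberately (the candidates are sums of the same small set
of rationals, and the smallest-id fallback makes any near-tie outcome
deterministic either way).

## Known limitations

* Directed graphs, multigraphs and overlapping communities are out of
  scope; weighted graphs are supported for propagation but not for
  modularity.
* The strict-LI update has no keep-current preference, so on pathological
  symmetric inputs it can in principle cycle until `max_iter`; the result
  is then flagged `converged = False` rather than silently accepted.
* A deterministic algorithm is deterministically wrong when its fixed
  order is unlucky for a particular topology: stability is not accuracy,
  and the baselines occasionally beat the deterministic engine on a given
  run.
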