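# niblpa

Community detection in undirected networks by **node-influence based label
propagation** (NIBLPA), with the classic LPA and the k-shell-ordered KBLPA
baselines, partition metrics, and synthetic benchmark generators.

Complex networks — protein-interaction graphs, social networks, co-citation
graphs — organise into *communities* (modules): groups of nodes densely
connected inside and sparsely connected outside. Label propagation (LPA) is
one of the fastest ways to find them: give every node a unique label, then
repeatedly let each node adopt the label carried by the plurality of its
neighbours until labels stop changing. Its weakness is instability — the
random visit order and random tie-breaking can give a different partition
on every run.

NIBLPA removes both sources of randomness:

1. **Fixed update order by node influence.** With `Ks(i)` the k-shell
   index of node *i* and `d(j)` the degree of neighbour *j*,

       NI(i) = Ks(i) + α · Σ_{j∈N(i)} Ks(j) / d(j),      α ∈ [0, 1]

   Nodes are visited in descending NI (ties by node id), so core nodes
   propagate their labels first.

2. **Deterministic tie-breaking by label influence.** When several labels
   tie for the neighbour plurality (the set `l_max`), the node adopts

       c_i = argmax_{l ∈ l_max}  LI(l),   LI(l) = Σ_{j∈N(i), c_j=l} NI(j) / d(j)

   with exact LI ties resolved to the smallest label id. The sweep itself
   is asynchronous — updates are visible within the sweep — which is what
   prevents label oscillation on bipartite subgraphs.

The result is a fully deterministic algorithm at the same near-linear cost
as LPA.

## Worked example

The six-node network with two triangles {v1,v2,v3} and {v4,v5,v6} joined
by the edges v1–v4 and v3–v6:

```bash
$ niblpa influence toy.tsv --alpha 1
node    ks      ni
v1      2       4.333333
v2      2       3.333333
v3      2       4.333333
v4      2       4.333333
v5      2       3.333333
v6      2       4.333333

$ niblpa run --algorithm niblpa --input toy.tsv --output toy_memb.tsv
INFO niblpa.propagation: niblpa: alpha=1, 1 sweep(s), converged=True, 2 communities

$ cat toy_memb.tsv
node    community
v1      0
v2      0
v3      0
v4      1
v5      1
v6      1
```

Every node sits in the 2-shell, so with α = 1 the degree-3 nodes get
NI = 2 + (2/2 + 2/3 + 2/3) = 13/3 ≈ 4.333 and the degree-2 nodes
10/3 ≈ 3.333. That fixes the visit order v1, v3, v4, v6, v2, v5, and a
single sweep recovers the two triangles exactly — label-influence
tie-breaking makes v1 join the triangle side (its degree-2 neighbour v2
carries more influence per edge, LI = (10/3)/2 ≈ 1.667, than the degree-3
candidates at 13/9 ≈ 1.444).

Benchmarking all three engines on a ring of five K5 cliques (stochastic
engines averaged over 100 seeded runs, reported as mean with the maximum
deviation of any run from the mean):

```bash
$ niblpa bench --generator clique-ring -n 5 -m 5 --repeats 100 --seed 1 2>/dev/null
network               algorithm  alpha     runs  nmi_mean  nmi_maxdev  f1_mean   f1_maxdev  q_mean    q_maxdev  converged_all
clique-ring(n=5,m=5)  niblpa     1.000000  1     1.000000  0.000000    1.000000  0.000000   0.709091  0.000000  True
clique-ring(n=5,m=5)  lpa                  100   0.993402  0.087656    0.986000  0.186000   0.704764  0.057491  True
clique-ring(n=5,m=5)  kblpa                100   0.965687  0.223204    0.931810  0.360381   0.685673  0.180218  True
```

NIBLPA recovers the planted cliques exactly and with zero spread; the
stochastic baselines are close on average but fluctuate run to run.

Other subcommands: `niblpa kshell`, `niblpa synth clique-ring`,
`niblpa synth planted`, `niblpa eval --graph G --pred P --truth T`.
Inputs are whitespace-delimited edge lists (`#` comments, optional third
weight column); partitions are TSV membership files (`node<TAB>community`).

## Library use

```python
import niblpa

G, truth = niblpa.clique_ring(5, 5)
result = niblpa.run_niblpa(G, alpha=1.0)
print(result.iterations, niblpa.nmi(result.partition, truth))  # 1 1.0
```

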