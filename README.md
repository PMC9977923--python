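# modanneal

Community detection in weighted undirected networks — brain connectomes,
social networks, any graph with mesoscale structure — by **modularity
maximization recast as ground-state search of a spin system**, solved with
a simulated-annealing sampler, plus the spectral and statistical tooling
needed to choose the community-count bound and to benchmark the result
against the Louvain heuristic.

It is written for network scientists who want (a) a modularity optimizer
whose objective and encoding are exactly specified and testable, (b) a
clean hand-off format for external discrete annealers (hardware or hybrid
solvers), and (c) a reproducible repeated-run benchmarking harness.

## The method

For a weighted undirected graph with adjacency `A` (symmetric, zero
diagonal), weighted degrees `g_i = Σ_j A_ij` and total weight `2m = Σ_i g_i`,
the modularity of a partition `c` at resolution `γ` is

    Q = (1/2m) Σ_ij B_ij δ(c_i, c_j),      B_ij = A_ij − γ g_i g_j / 2m.

`Q` compares the edge weight inside communities with what a
degree-preserving random rewiring would place there. Maximizing `Q` is
equivalent to finding the ground state of a k-state Potts glass

    E(c) = − Σ_{i<j} J_ij δ(c_i, c_j),      J = B (off-diagonal),

since `Q = (−2E + tr B) / 2m` exactly; for two communities this reduces to
an Ising model over spins `s_i ∈ {−1, +1}`. The same objective is exposed
as a one-hot **discrete quadratic model** (variables with `k` cases,
same-case bias `−B_ij`) — the representation discrete annealing hardware
consumes. The package ships:

* a Metropolis simulated-annealing sampler (geometric cooling, independent
  restarts, bit-reproducible from a seed) and an exact-enumeration oracle
  for small instances;
* the eigengap heuristic on the normalized graph Laplacian to propose the
  community-count bound `k_max` (the largest of the three top-gap
  candidates);
* a Louvain baseline and repeated-run comparison statistics: one-sided
  Welch's t-test, Cohen's d, and percentage relative increase with
  propagated SEM;
* a planted-partition generator with adjusted-Rand-index scoring, and the
  Zachary karate-club network (weighted and binary) as a bundled fixture.

## Worked example

The karate-club network (34 members, weighted friendship ties, a documented
two-faction split). First let the eigengap heuristic rank community counts:

```text
$ modanneal eigengap --input karate.tsv
rank  k     gap
   1  4     0.2249
   2  2     0.1548
   3  3     0.1003
k_max = 4
```

The three largest gaps sit at k = 4, 2, 3; the bound handed to the
optimizer is the largest, `k_max = 4`. Detect communities under that bound:

```text
$ modanneal detect --input karate.tsv --kmax eigengap --seed 1
Q = 0.445  communities = 4  (k_max = 4)
```

The annealer fills all four allowed communities and reaches
Q = 0.444904 — the maximum-modularity partition of the weighted graph at
γ = 1, k ≤ 4 (tabulated as 0.444 at truncated 3 d.p. in the literature).
Benchmark it against Louvain over repeated runs:

```text
$ modanneal compare --input karate.tsv --kmax 4 --runs 20 --restarts 50 --seed 1
algorithm   Q (mean ± std)        communities
anneal      0.445 ± 0.000      4.00
louvain     0.443 ± 0.005      4.00
one-sided Welch t = 1.886 (df = 19.0), p = 0.0374
Cohen's d = 0.596; relative increase = 0.508 ± 0.271 %
```

The annealer is essentially deterministic (it finds the same optimum from
every seed) while Louvain's greedy moves scatter below it; the one-sided
Welch test says the mean difference is significant at p < 0.05, and the
relative increase quantifies it as ~0.5 % for this run size. With 100 runs
(the default) Louvain lands at 0.440 ± 0.007 and the gap widens.

The same pipeline accepts dense CSV adjacencies and BrainNet-Viewer
`.edge`/`.node` connectome files (`--format csv|brainnet`, optional
`--threshold` binarization), so atlas-based brain networks run unchanged.

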