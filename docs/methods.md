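# Methods

## Objective and encodings

The package maximizes Newman–Girvan modularity at resolution γ over
partitions of a weighted undirected graph into at most `k_max`
communities. Three algebraically equivalent expressions are implemented
and cross-checked to 1e−12 in the test suite: the per-community form
(within-weight and degree sums), the Kronecker quadratic form over the
modularity matrix `B = A − γ g gᵀ/2m`, and the two-state spin form.
Two conventions make the equivalences exact and are worth stating:

* within-community weight `l_s` counts each edge once (the raw double sum
  over a community counts it twice);
* the diagonal of `B` is kept in the quadratic forms — it is a
  partition-independent constant `−γ Σ g_i²/2m`, but dropping it silently
  would break the per-community ⇔ Kronecker identity;
* the spin form is implemented as `(1/4m) Σ B_ij (s_i s_j + 1)`. The `+1`
  term is a constant `(1−γ)/2` that vanishes at γ = 1; keeping it makes
  the spin form the exact k = 2 specialization of the Kronecker form at
  every γ rather than only at γ = 1.

Optimization goes through energy models constructed so that **lower
energy is higher modularity**: Potts couplings `J = B` (off-diagonal)
with `E(c) = −Σ_{i<j} J_ij δ(c_i,c_j)`, giving `Q = (−2E + tr B)/2m`
exactly; the Ising special case `J = B/2m` with recorded constant offset;
and a one-hot discrete quadratic model with same-case bias `−B_ij` whose
sample energies coincide with the Potts energies state by state. Global
positive factors (1/m) and constant offsets are dropped from stored
couplings — they cannot move the argmin — but every dropped constant is
recorded on the model so the exact energy↔modularity identity stays
testable. Couplings are stored dense: the null-model term makes `B`
dense regardless of graph sparsity, so a pair-keyed sparse map would
only add overhead (the JSON hand-off format for external solvers does
use an explicit pair → bias map).

A deliberate point of care: conventions in which the coupling is written
as `−B/2m` under an energy `−½ Σ J s s` make energy *minimization*
minimize modularity. This package fixes the operational contract
`argmin E = argmax Q` and signs everything accordingly; the contract is
what the samplers, tests and benchmark results all rely on.

## Samplers

**Exact enumeration** evaluates every canonical (first-occurrence-ordered)
labeling for `k^n ≤ 1e7`, visiting them in lexicographic order so ties
resolve deterministically to the smallest canonical labeling. It is the
oracle for all stochastic-sampler tests.

**Simulated annealing** performs single-variable Metropolis updates:
propose a uniform random new community for a uniform random node, accept
if `ΔE ≤ 0`, else with probability `exp(−ΔE/T)`. `ΔE` is computed
incrementally from one coupling row in O(n) (validated against full
re-evaluation to 1e−9). The schedule is geometric: defaults
`T_start = 1.0`, `T_end = 1e−3`, `cooling_factor = 0.95` (≈136
temperatures), `10·n` proposals per temperature, and 100 independent
restarts, restart r seeded `seed + r` from a single master seed so runs
are bit-reproducible across platforms (all randomness is pre-drawn from
`numpy.random.default_rng`; the inner chain is JIT-compiled with numba).
These defaults were chosen so that best-of-20 restarts reproduces the
enumeration oracle on random 8-node instances with margin and a
best-of-100 run on a 34-node graph takes well under a second; they are
configuration, not tuned constants of the method.

**External backends** plug in through a registered adapter that consumes
the DQM JSON dump and returns one case per variable; outputs are
validated and re-scored locally, so a backend can never report an
inconsistent modularity.

Returned partitions may leave communities empty — `k_max` is a bound,
not a target — and every result's modularity is recomputed from the
partition through the exact identity rather than read off the search.

## Choosing k_max: the eigengap heuristic

Eigenvalues of the symmetric normalized Laplacian
`I − D^{−1/2} A D^{−1/2}` are sorted ascending and the heuristic ranks
`k` by the gap `λ_{k+1} − λ_k` over `k ∈ [2, ⌈n/2⌉]`; the top three are
candidates and the largest candidate becomes `k_max`. Choices made here,
since the operator and weight handling are genuinely open:

* the operator defaults to the **binarized** connectivity pattern. On
  the weighted karate network the weighted spectrum ranks k = 3 first,
  while the binary spectrum ranks k = 4 first with {2, 3, 4} as the
  top-3 set — the configuration consistent with the known mesoscale
  structure of that network; the weighted variant stays available via
  `weights="weighted"`.
* gaps in the trailing half of the spectrum are excluded: large gaps
  near `k = n` reflect near-singleton clusters, which are not the object
  of interest.
* degree-0 nodes are removed (with a warning) before normalization;
  ties between equal gaps go to the smaller k.

For c disjoint equal cliques the zero eigenvalue has multiplicity c and
the heuristic provably returns c; one added inter-clique edge does not
change it (both are tested for c up to 6).

## Baseline and comparison statistics

The baseline is the Louvain implementation in networkx with default
parameters, γ passed as `resolution` and the partition's modularity
recomputed internally. Ensembles of R runs (default 100) use derived
seeds `master + r·100000` so annealing restart streams never overlap
across runs. Comparison of ensembles a (annealer) vs b (baseline):

* one-sided Welch t with Welch–Satterthwaite degrees of freedom,
  H1: mean_a > mean_b; p from the t survival function. The annealer is
  near-deterministic, so the zero-variance edge is defined explicitly:
  both variances zero ⇒ p = 0.5 for equal means, else 0 or 1 by sign.
* Cohen's d with the equal-n pooling `√((s_a² + s_b²)/2)`.
* relative increase `100·(x̄_a − x̄_b)/x̄_b` with first-order propagation
  of both SEMs.

The Welch routine is cross-checked against `scipy.stats.ttest_ind`
(`equal_var=False, alternative="greater"`) to 1e−10 on random ensembles.

## Synthetic data and fixtures

The planted-partition generator draws independent Bernoulli edges at
`p_in` within and `p_out` between equal blocks (remainder round-robin),
optional edge weights uniform on [0.5, 1.5], fully seeded. It emulates
the block-structured, integration–segregation organization the detector
targets; it does **not** emulate heavy-tailed degree sequences,
hierarchical or overlapping communities, or the spatial embedding of
real connectomes, so passing recovery tests demonstrates correct
optimization of the objective on block-structured graphs, not
performance on arbitrary real networks. The reference recovery setting
(n = 60, 3 blocks, p_in = 0.3, p_out = 0.02) gives mean within-degree
≈ 5.7 vs between ≈ 0.8; note that at these sizes the *maximum-modularity*
partition itself disagrees with the planted labels at one boundary node
in roughly a third of draws (one node out of 60 puts ARI at 0.9496), a
property of the objective on sparse blocks, not of the sampler.

The Zachary karate club ships as plain-text data in the original
weighted form (2m = 462) and the binary 78-edge form. Two faction
labelings are provided: the *observed* post-fission membership, and the
*network-flow* (minimum-cut) partition, which differ only in individual
9. The distinction matters: flipping individual 9 toward the officers'
side strictly increases modularity at every γ on both graph forms, so a
max-modularity bipartition can recover the flow partition exactly (it
does, at γ = 0.5 with k_max = 2) but can never reproduce the observed
membership — individual 9's real affiliation was set by circumstances
outside the friendship network. The supervised-recovery demonstration
therefore scores against the flow partition, and γ = 0.5 is the package's
chosen sub-unit resolution (any γ in the scanned range 0.3–0.95 gives the
same bipartition; γ = 0.5 also makes unconstrained Louvain return exactly
two communities, enabling a like-for-like comparison).

## Numerical choices and limitations

* Degenerate inputs: edgeless graphs are rejected wherever `2m` enters a
  denominator; self-loops are dropped on read (the adjacency contract
  forces a zero diagonal) with a counted warning; `k_max = 1` returns
  the trivial partition with a warning.
* Symmetry tolerance for matrix inputs is 1e−9; beyond it the file is
  rejected rather than silently symmetrized.
* Equal-energy ties: exact sampler → lexicographically smallest
  canonical labeling; annealing → first restart found.
* Modularity values are reported at full precision and displayed to 3
  decimals in tables.
* Scale: the dense `B` and the O(n) per-move kernel are comfortable to a
  few thousand nodes; beyond that, the DQM export plus an external
  solver is the intended route. Exhaustive enumeration is guarded at
  `k^n ≤ 1e7`.
* The sampler certifies nothing: simulated annealing is a heuristic, and
  agreement with the enumeration oracle is established only on small
  instances. On larger graphs "best of R restarts" is an empirical, not
  a provable, optimum.
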