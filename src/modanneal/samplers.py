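"""Ground-state search for the Potts/DQM energy models.

Three routes are provided:

* :func:`exact_ground_state` — exhaustive enumeration of labelings for
  tiny instances; the oracle every stochastic sampler is tested against.
* :func:`simulated_annealing` — single-variable Metropolis dynamics under
  a geometric cooling schedule with independent restarts; the desk-scale
  stand-in for a physical annealer.
* an external-backend slot (:func:`register_backend`) consuming the DQM
  JSON hand-off format, for plugging in hardware or hybrid solvers.

All routes return a :class:`SampleResult` whose modularity is recomputed
from the partition via the exact energy identity, never trusted from the
search itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energies import DQModel, PottsModel, build_dqm, build_potts
from .graph import WeightedGraph, canonicalize_labels
from .modularity import ModularityConfig, Partition, modularity_matrix

__all__ = [
    "AnnealSchedule",
    "SampleResult",
    "exact_ground_state",
    "simulated_annealing",
    "detect_communities",
    "register_backend",
]

_EXACT_GUARD = 10_000_000


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for the Metropolis sampler.

    Temperature starts at ``T_start`` and is multiplied by
    ``cooling_factor`` until it drops below ``T_end``; at each temperature
    ``sweeps_per_temperature`` single-variable proposals are made (the
    default, 0, means 10*n proposals).  ``restarts`` independent chains are
    run from uniform random initial labelings, restart r seeded with
    ``seed + r``; the best-energy final state wins.
    """

    T_start: float = 1.0
    T_end: float = 1e-3
    cooling_factor: float = 0.95
    sweeps_per_temperature: int = 0  # 0 -> 10 * n
    restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.T_start > self.T_end > 0):
            raise ValueError("need T_start > T_end > 0")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    def temperatures(self) -> np.ndarray:
        n_steps = int(np.floor(np.log(self.T_end / self.T_start)
                               / np.log(self.cooling_factor))) + 1
        return self.T_start * self.cooling_factor ** np.arange(n_steps)


@dataclass
class SampleResult:
    """Outcome of one ground-state search."""

    partition: Partition
    energy: float
    modularity: float
    n_communities_nonempty: int
    restart_index: int = 0
    seed: int = 0
    restart_energies: list = field(default_factory=list)  # best final E per restart

    def to_dict(self) -> dict:
        return {
            "labels": self.partition.labels.tolist(),
            "k_max": self.partition.k_max,
            "energy": self.energy,
            "modularity": self.modularity,
            "n_communities_nonempty": self.n_communities_nonempty,
            "restart_index": self.restart_index,
            "seed": self.seed,
        }


def _result_from_labels(model: PottsModel, labels: np.ndarray,
                        restart_index: int = 0, seed: int = 0,
                        restart_energies: list | None = None) -> SampleResult:
    labels = canonicalize_labels(np.asarray(labels, dtype=int))
    part = Partition(labels, k_max=model.k)
    E = model.energy(labels)
    return SampleResult(
        partition=part,
        energy=E,
        modularity=model.modularity_from_energy(E),
        n_communities_nonempty=part.n_communities,
        restart_index=restart_index,
        seed=seed,
        restart_energies=restart_energies or [],
    )


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------

def _is_canonical(labels: tuple[int, ...]) -> bool:
    seen_max = -1
    for lab in labels:
        if lab > seen_max + 1:
            return False
        seen_max = max(seen_max, lab)
    return True


def exact_ground_state(model: PottsModel) -> SampleResult:
    """Globally optimal partition by exhaustive enumeration of k^n labelings.

    Only labelings already in canonical first-occurrence form are
    evaluated (one representative per label-permutation class), and they
    are visited in lexicographic order, so among degenerate ground states
    the lexicographically smallest canonical labeling is returned.
    Refuses instances with k^n above 1e7.
    """
    n, k = model.n, model.k
    if k ** n > _EXACT_GUARD:
        raise ValueError(
            f"exact enumeration refused: k^n = {k}^{n} exceeds the {_EXACT_GUARD:.0e} guard"
        )
    J = model.J
    best_E = np.inf
    best: tuple[int, ...] | None = None
    for labels in itertools.product(range(k), repeat=n):
        if not _is_canonical(labels):
            continue
        c = np.asarray(labels)
        same = c[:, None] == c[None, :]
        E = -0.5 * float((J * same).sum())  # J diagonal is zero
        if E < best_E - 1e-12:
            best_E = E
            best = labels
    assert best is not None
    return _result_from_labels(model, np.array(best))


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------

@njit(cache=True)
def _metropolis_chain(J, labels, k, temps, moves_per_temp, rand_i, rand_case, rand_u):
    """In-place Metropolis chain; returns the final energy.

    Delta-E for moving node i from case a to case b is computed
    incrementally from row i of J in O(n), never by full re-evaluation.
    """
    n = labels.shape[0]
    move = 0
    for t in range(temps.shape[0]):
        T = temps[t]
        for _ in range(moves_per_temp):
            i = rand_i[move]
            b = rand_case[move]
            a = labels[i]
            if a != b:
                dE = 0.0
                for j in range(n):
                    if j == i:
                        continue
                    if labels[j] == b:
                        dE -= J[i, j]
                    elif labels[j] == a:
                        dE += J[i, j]
                if dE <= 0.0 or rand_u[move] < np.exp(-dE / T):
                    labels[i] = b
            move += 1
    E = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                E -= J[i, j]
    return E


def simulated_annealing(model: PottsModel, schedule: AnnealSchedule | None = None) -> SampleResult:
    """Best-of-restarts Metropolis annealing on a Potts model.

    Fully reproducible: restart r draws its initial labeling and proposal
    stream from ``numpy.random.default_rng(schedule.seed + r)``.  The
    returned result is the lowest-final-energy restart (ties keep the
    first found).
    """
    schedule = schedule or AnnealSchedule()
    n, k = model.n, model.k
    temps = schedule.temperatures()
    moves_per_temp = schedule.sweeps_per_temperature or 10 * n
    total_moves = temps.size * moves_per_temp
    J = np.ascontiguousarray(model.J)

    best_E = np.inf
    best_labels: np.ndarray | None = None
    best_restart = 0
    per_restart: list[float] = []
    for r in range(schedule.restarts):
        rng = np.random.default_rng(schedule.seed + r)
        labels = rng.integers(0, k, n).astype(np.int64)
        rand_i = rng.integers(0, n, total_moves)
        rand_case = rng.integers(0, k, total_moves)
        rand_u = rng.random(total_moves)
        E = _metropolis_chain(J, labels, k, temps, moves_per_temp, rand_i, rand_case, rand_u)
        per_restart.append(float(E))
        if E < best_E - 1e-12:
            best_E = E
            best_labels = labels.copy()
            best_restart = r
    assert best_labels is not None
    return _result_from_labels(model, best_labels, restart_index=best_restart,
                               seed=schedule.seed, restart_energies=per_restart)


# ---------------------------------------------------------------------------
# external backend slot + end-to-end driver
# ---------------------------------------------------------------------------

_EXTERNAL_BACKEND = None


def register_backend(adapter) -> None:
    """Register an external DQM solver.

    ``adapter`` must accept the DQM JSON dump (str) and return one case
    index per variable; results are validated and re-scored locally.
    """
    global _EXTERNAL_BACKEND
    _EXTERNAL_BACKEND = adapter


def _run_external(model: PottsModel, dqm: DQModel) -> SampleResult:
    if _EXTERNAL_BACKEND is None:
        raise RuntimeError("backend='external' but no adapter registered (register_backend)")
    raw = _EXTERNAL_BACKEND(dqm.to_json())
    labels = np.asarray(list(raw), dtype=int)
    if labels.shape != (model.n,):
        raise ValueError(f"adapter returned {labels.shape[0] if labels.ndim else '?'} labels "
                         f"for {model.n} variables")
    if labels.size and (labels.min() < 0 or labels.max() >= model.k):
        raise ValueError(f"adapter returned case outside [0, {model.k - 1}]")
    return _result_from_labels(model, labels)


def detect_communities(
    graph: WeightedGraph,
    k_max: int,
    config: ModularityConfig | None = None,
    schedule: AnnealSchedule | None = None,
    backend: str = "sa",
) -> SampleResult:
    """End-to-end detection: modularity matrix -> Potts/DQM -> sampler.

    Empty communities are allowed, so the returned partition may use
    fewer than ``k_max`` labels.
    """
    config = config or ModularityConfig()
    modmat = modularity_matrix(graph, config)
    if k_max == 1:
        import warnings

        warnings.warn("k_max=1 is degenerate; returning the single-community partition")
        model = build_potts(modmat, 2)
        return _result_from_labels(model, np.zeros(graph.n, dtype=int))
    model = build_potts(modmat, k_max)
    if backend == "sa":
        return simulated_annealing(model, schedule)
    if backend == "exact":
        return exact_ground_state(model)
    if backend == "external":
        return _run_external(model, build_dqm(modmat, k_max))
    raise ValueError(f"unknown backend {backend!r}")
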