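"""Energy-model encodings of modularity maximization.

Maximizing modularity is recast as finding the ground state of a spin
system: an Ising model (2 communities), a k-state Potts model, or the
one-hot Discrete Quadratic Model (DQM) form that discrete annealers
consume.  All three share the convention that **lower energy means
higher modularity**, so any energy minimizer is a modularity maximizer.

Constant offsets (the diagonal of B, global 1/m factors) do not change
the ground state and are dropped from the stored couplings, but each
model records what was dropped so the exact energy<->modularity identity
remains testable:

* Potts / DQM:  Q(c) = (-2 E(c) + trace(B)) / 2m,
  with E(c) = -sum_{i<j} J_ij delta(c_i, c_j) and J = B (off-diagonal).
* Ising (k=2):  Q(s) = -E(s) + trace(B)/4m,
  with E(s) = -(1/2) sum_ij J_ij s_i s_j and J = B/2m (off-diagonal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .modularity import ModularityMatrix

__all__ = ["IsingModel", "PottsModel", "DQModel", "build_ising", "build_potts", "build_dqm"]


@dataclass
class IsingModel:
    """Two-state spin glass with E(s) = -sum_i h_i s_i - (1/2) sum_ij J_ij s_i s_j.

    For graph models h = 0 (no external field) and J has a zero diagonal;
    ``offset`` is the constant making E(s) = -Q(s) + offset exact.
    """

    h: np.ndarray
    J: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if not np.allclose(self.J, self.J.T):
            raise ValueError("coupling matrix J must be symmetric")

    @property
    def n(self) -> int:
        return self.J.shape[0]

    def energy(self, spins: np.ndarray) -> float:
        s = np.asarray(spins, dtype=float)
        if not np.all(np.isin(s, (-1.0, 1.0))):
            raise ValueError("spins must be -1 or +1")
        return float(-self.h @ s - 0.5 * s @ self.J @ s)


@dataclass
class PottsModel:
    """k-state Potts glass with E(c) = -sum_{i<j} J_ij delta(c_i, c_j).

    ``trace_B`` and ``two_m`` are the recorded constants of the modularity
    identity Q = (-2E + trace_B) / two_m.
    """

    J: np.ndarray
    k: int
    trace_B: float
    two_m: float

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.k < 2:
            raise ValueError(f"Potts model needs k >= 2, got {self.k}")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("coupling matrix J must be symmetric")

    @property
    def n(self) -> int:
        return self.J.shape[0]

    def energy(self, labels: np.ndarray) -> float:
        c = np.asarray(labels, dtype=int)
        same = c[:, None] == c[None, :]
        off = same & ~np.eye(self.n, dtype=bool)
        return float(-0.5 * (self.J * off).sum())

    def modularity_from_energy(self, energy: float) -> float:
        return (-2.0 * energy + self.trace_B) / self.two_m


@dataclass
class DQModel:
    """One-hot discrete quadratic model over n variables with k cases each.

    Variable i is the indicator vector x_i with x_iu = 1 iff node i is in
    community u (constraint sum_u x_iu = 1; spin view s_iu = 2 x_iu - 1).
    Only same-case quadratic biases are nonzero: bias(i,u; j,u) = -B_ij,
    and all linear biases are zero (no external field).  Sample energy is
    E(c) = sum_{i<j} q_ij delta(c_i, c_j), identical to the Potts energy.
    """

    n: int
    k: int
    quadratic: np.ndarray  # q_ij = -B_ij, zero diagonal (no self-couplings)
    linear: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"DQM needs k >= 2, got {self.k}")
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        if self.linear is None:
            self.linear = np.zeros((self.n, self.k))
        if np.any(np.diag(self.quadratic) != 0):
            raise ValueError("DQM must not contain self-couplings")

    def energy(self, labels: np.ndarray) -> float:
        c = np.asarray(labels, dtype=int)
        same = c[:, None] == c[None, :]
        off = same & ~np.eye(self.n, dtype=bool)
        return float(0.5 * (self.quadratic * off).sum()) + float(
            self.linear[np.arange(self.n), c].sum()
        )

    # -- hand-off format for external annealer backends --------------------
    def to_json(self) -> str:
        pairs = {}
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.quadratic[i, j] != 0.0:
                    pairs[f"{i},{j}"] = self.quadratic[i, j]
        return json.dumps(
            {"variables": self.n, "cases": self.k, "same_case_bias": pairs},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DQModel":
        obj = json.loads(text)
        n, k = int(obj["variables"]), int(obj["cases"])
        q = np.zeros((n, n))
        for key, bias in obj["same_case_bias"].items():
            i, j = (int(t) for t in key.split(","))
            q[i, j] = q[j, i] = float(bias)
        return cls(n=n, k=k, quadratic=q)


def build_ising(modmatrix: ModularityMatrix) -> IsingModel:
    """Ising encoding of the 2-community problem: J = B/2m off-diagonal.

    The dropped diagonal makes the exact identity
    ``energy(s) = -modularity_ising(s) + offset`` with
    ``offset = trace(B) / 4m``.
    """
    two_m = 2.0 * modmatrix.m
    J = modmatrix.B / two_m
    np.fill_diagonal(J, 0.0)
    # trace term: dropped diagonal of B; B.sum() term: the (s_i s_j + 1)
    # indicator constant, nonzero only away from gamma = 1
    offset = (modmatrix.trace + modmatrix.B.sum()) / (2.0 * two_m)
    return IsingModel(h=np.zeros(modmatrix.n), J=J, offset=offset)


def build_potts(modmatrix: ModularityMatrix, k: int) -> PottsModel:
    """Potts encoding for up to k communities: J = B off-diagonal.

    The global 1/m factor is a positive rescaling of the energy and is
    dropped; the ground-state set is unchanged.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    J = modmatrix.B.copy()
    np.fill_diagonal(J, 0.0)
    return PottsModel(J=J, k=k, trace_B=modmatrix.trace, two_m=2.0 * modmatrix.m)


def build_dqm(modmatrix: ModularityMatrix, k_max: int) -> DQModel:
    """One-hot DQM with same-case bias -B_ij between distinct variables."""
    if k_max < 2:
        raise ValueError(f"k_max must be >= 2, got {k_max}")
    q = -modmatrix.B.copy()
    np.fill_diagonal(q, 0.0)
    return DQModel(n=modmatrix.n, k=k_max, quadratic=q)
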