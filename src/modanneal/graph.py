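"""Weighted-graph container and file I/O.

The central object is :class:`WeightedGraph`, a symmetric nonnegative
adjacency matrix with a zero diagonal — the contract every downstream
modularity computation relies on.  Readers are provided for edge lists
(TSV/CSV ``source, target[, weight]``), dense adjacency matrices (CSV),
and BrainNet-Viewer-style ``.edge`` / ``.node`` files used to distribute
brain connectomes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WeightedGraph",
    "GraphFormatError",
    "load_edge_list",
    "load_adjacency",
    "load_brainnet_nodes",
    "write_partition",
    "read_partition",
    "write_edge_list",
    "canonicalize_labels",
]

_SYMMETRY_TOL = 1e-9


class GraphFormatError(ValueError):
    """Raised when an input file violates the graph format contract."""


@dataclass
class WeightedGraph:
    """An undirected weighted graph held as a dense adjacency matrix.

    Invariants (checked by :meth:`validate`): the adjacency is symmetric,
    has a zero diagonal (no self-loops), and all weights are nonnegative.
    ``weighted=False`` declares that all weights are 0/1.
    """

    node_ids: list[str]
    adjacency: np.ndarray
    weighted: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.node_ids = [str(x) for x in self.node_ids]
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree g_i = sum_j A_ij."""
        return self.adjacency.sum(axis=1)

    @property
    def total_weight_2m(self) -> float:
        """2m = sum_i g_i = sum_ij A_ij."""
        return float(self.adjacency.sum())

    def validate(self) -> None:
        A = self.adjacency
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise GraphFormatError(f"adjacency must be square, got shape {A.shape}")
        if A.shape[0] != len(self.node_ids):
            raise GraphFormatError(
                f"{len(self.node_ids)} node ids for a {A.shape[0]}x{A.shape[1]} matrix"
            )
        if np.isnan(A).any():
            raise GraphFormatError("adjacency contains NaN entries")
        if not np.allclose(A, A.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise GraphFormatError("adjacency is not symmetric")
        if np.any(np.diag(A) != 0.0):
            raise GraphFormatError("adjacency has nonzero diagonal (self-loops)")
        if np.any(A < 0.0):
            raise GraphFormatError("adjacency has negative weights")
        if not self.weighted:
            vals = np.unique(A)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise GraphFormatError("weighted=False but weights outside {0,1}")

    # -- convenience -------------------------------------------------------
    def binarized(self, threshold: float = 0.0) -> "WeightedGraph":
        """Return the 0/1 connectivity pattern: w_ij <- 1 if w_ij > threshold."""
        A = (self.adjacency > threshold).astype(float)
        return WeightedGraph(list(self.node_ids), A, weighted=False, meta=dict(self.meta))

    def index_of(self, node: str) -> int:
        return self.node_ids.index(str(node))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_delimiter(sample: str) -> str | None:
    """Return ',' or tab if present; None means any-whitespace splitting."""
    if "\t" in sample:
        return "\t"
    if "," in sample:
        return ","
    return None


def load_edge_list(
    path: str | Path,
    directed_policy: str = "symmetrize",
) -> WeightedGraph:
    """Read a ``source target [weight]`` edge list into a WeightedGraph.

    Nodes are ordered by first appearance.  A missing weight column means
    weight 1.  Duplicate (i, j) entries are summed.  Self-loops are dropped
    (the adjacency contract forces A_ii = 0) and counted in
    ``meta["dropped_self_loops"]``.

    Parameters
    ----------
    directed_policy:
        ``"symmetrize"`` treats each row as an undirected edge contribution
        (weights for (i, j) and (j, i) are accumulated into the same entry);
        ``"error"`` additionally rejects files where (i, j) and (j, i) both
        appear with different accumulated weights.
    """
    if directed_policy not in ("symmetrize", "error"):
        raise ValueError(f"unknown directed_policy {directed_policy!r}")
    path = Path(path)
    order: list[str] = []
    index: dict[str, int] = {}
    # accumulate directed weights first so the 'error' policy can compare them
    directed: dict[tuple[int, int], float] = {}
    self_loops = 0
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            delim = _sniff_delimiter(line)
            parts = [p.strip() for p in (line.split(delim) if delim else line.split())]
            parts = [p for p in parts if p]
            if len(parts) < 2:
                raise GraphFormatError(f"{path}:{lineno}: expected >=2 columns, got {parts!r}")
            src, dst = parts[0], parts[1]
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise GraphFormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            else:
                w = 1.0
            if w < 0:
                raise GraphFormatError(f"{path}:{lineno}: negative weight {w}")
            for node in (src, dst):
                if node not in index:
                    index[node] = len(order)
                    order.append(node)
            i, j = index[src], index[dst]
            if i == j:
                self_loops += 1
                continue
            directed[(i, j)] = directed.get((i, j), 0.0) + w

    n = len(order)
    A = np.zeros((n, n))
    seen_weights: set[float] = set()
    # duplicate same-direction entries were summed above; the two directions
    # of one undirected edge are merged (their mean), so (a,b,2),(b,a,2) is a
    # single edge of weight 2
    for i, j in {(min(i, j), max(i, j)) for (i, j) in directed}:
        vals = [directed[d] for d in ((i, j), (j, i)) if d in directed]
        if directed_policy == "error" and len(vals) == 2:
            if not np.isclose(vals[0], vals[1], atol=_SYMMETRY_TOL):
                raise GraphFormatError(
                    f"asymmetric weights for edge ({order[i]}, {order[j]}): "
                    f"{vals[0]} vs {vals[1]}"
                )
        w = float(np.mean(vals))
        A[i, j] = A[j, i] = w
        seen_weights.add(w)
    weighted = not seen_weights <= {1.0}
    meta = {"source": str(path), "dropped_self_loops": self_loops}
    return WeightedGraph(order, A, weighted=weighted, meta=meta)


def _parse_numeric_table(text: str, delimiter: str | None) -> tuple[np.ndarray, list[str] | None]:
    """Parse a possibly-labeled numeric table; return (matrix, row labels or None)."""
    rows: list[list[str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if delimiter:
            rows.append([c.strip() for c in line.split(delimiter)])
        else:
            rows.append(line.split())
    if not rows:
        raise GraphFormatError("empty matrix file")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = rows[0] if not all(_is_number(t) for t in rows[0] if t) else None
    body = rows[1:] if header is not None else rows
    labels: list[str] | None = None
    first_col = [r[0] for r in body if r]
    if first_col and not all(_is_number(t) for t in first_col):
        labels = first_col
        body = [r[1:] for r in body]
    try:
        M = np.array([[float(t) for t in r if t != ""] for r in body], dtype=float)
    except ValueError as exc:
        raise GraphFormatError(f"non-numeric entry in matrix: {exc}") from exc
    return M, labels


def load_adjacency(
    path: str | Path,
    format: str = "csv",
    binarize_threshold: float | None = None,
) -> WeightedGraph:
    """Read a dense adjacency matrix (CSV or BrainNet ``.edge`` dialect).

    The matrix must be square and symmetric to 1e-9; the diagonal is
    forcibly zeroed (count in ``meta["zeroed_diagonal"]``).  With
    ``binarize_threshold`` set, weights become 1 where ``w > threshold``
    and 0 elsewhere.
    """
    if format not in ("csv", "brainnet_edge"):
        raise ValueError(f"unknown adjacency format {format!r}")
    path = Path(path)
    text = path.read_text()
    delim = "," if format == "csv" else None
    M, labels = _parse_numeric_table(text, delim)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise GraphFormatError(f"{path}: matrix is not square: {M.shape}")
    if np.isnan(M).any():
        raise GraphFormatError(f"{path}: matrix contains NaN")
    if not np.allclose(M, M.T, atol=_SYMMETRY_TOL, rtol=0.0):
        raise GraphFormatError(f"{path}: matrix not symmetric within 1e-9")
    M = 0.5 * (M + M.T)  # kill rounding-level asymmetry
    zeroed = int(np.count_nonzero(np.diag(M)))
    np.fill_diagonal(M, 0.0)
    weighted = True
    if binarize_threshold is not None:
        M = (M > binarize_threshold).astype(float)
        weighted = False
    elif set(np.unique(M)) <= {0.0, 1.0}:
        weighted = False
    node_ids = labels if labels is not None else [str(i) for i in range(M.shape[0])]
    meta = {"source": str(path), "zeroed_diagonal": zeroed}
    return WeightedGraph(node_ids, M, weighted=weighted, meta=meta)


def load_brainnet_nodes(path: str | Path) -> list[dict]:
    """Parse a BrainNet ``.node`` file (x y z color size label per row).

    Used only to annotate reports; coordinates never enter any computation.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise GraphFormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            x, y, z, color, size = (float(p) for p in parts[:5])
            out.append({"x": x, "y": y, "z": z, "color": color, "size": size,
                        "label": " ".join(parts[5:])})
    return out


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities by first occurrence: [2,2,0] -> [0,0,1]."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for pos, lab in enumerate(labels.tolist()):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[pos] = mapping[lab]
    return out


def write_partition(labels: np.ndarray, graph: WeightedGraph, path: str | Path) -> None:
    """Write ``node<TAB>community`` rows, labels canonicalized on write."""
    labels = np.asarray(labels)
    if len(labels) != graph.n:
        raise ValueError(f"partition length {len(labels)} != node count {graph.n}")
    canon = canonicalize_labels(labels) if len(labels) else labels
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node", "community"])
        for node, lab in zip(graph.node_ids, canon):
            writer.writerow([node, int(lab)])


def read_partition(path: str | Path, graph: WeightedGraph | None = None) -> np.ndarray:
    """Read a partition TSV back into a label vector (graph node order)."""
    by_node: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["node", "community"]:
            raise GraphFormatError(f"{path}: expected header 'node\\tcommunity'")
        for row in reader:
            if not row:
                continue
            by_node[row[0]] = int(row[1])
    if graph is None:
        return np.array(list(by_node.values()), dtype=int)
    try:
        return np.array([by_node[node] for node in graph.node_ids], dtype=int)
    except KeyError as exc:
        raise GraphFormatError(f"{path}: node {exc} missing from partition file") from exc


def write_edge_list(graph: WeightedGraph, path: str | Path) -> None:
    """Write the graph as a TSV edge list (upper triangle, weights kept)."""
    A = graph.adjacency
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i in range(graph.n):
            for j in range(i + 1, graph.n):
                if A[i, j] != 0.0:
                    w = A[i, j]
                    writer.writerow([graph.node_ids[i], graph.node_ids[j],
                                     int(w) if w == int(w) else w])
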