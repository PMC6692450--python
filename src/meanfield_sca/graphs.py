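"""Graph families for the cellular-automaton dynamics.

Three undirected topologies are supported, mirroring the three network
structures used throughout the package:

* a square **torus grid** with von-Neumann (4-neighbor) connectivity, so every
  node's self-inclusive neighborhood has size 5;
* an **Erdős–Rényi random graph** ``G(n, p_e)`` where every unordered pair is
  an edge independently with probability ``p_e``;
* a **Newman–Watts small-world graph**: the torus grid plus shortcut edges,
  each non-grid pair added independently with probability ``p_w`` (edges are
  added, never rewired or removed).

Node identifiers are 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Graph",
    "GraphSpec",
    "make_torus_grid",
    "make_random_graph",
    "make_smallworld",
    "neighborhood",
    "make_graph",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
]

GRID = "grid"
RANDOM = "random"
SMALLWORLD = "smallworld"
KINDS = (GRID, RANDOM, SMALLWORLD)


@dataclass
class Graph:
    """Undirected graph with contiguous 0-based node ids.

    ``neighbors[i]`` is a sorted integer array of the nodes adjacent to ``i``
    (self-loops are never stored). ``meta`` records how the graph was built,
    including the seed for the random families.
    """

    n: int
    neighbors: list[np.ndarray]
    kind: str = "custom"
    meta: dict = field(default_factory=dict)

    def degree(self, i: int | None = None):
        if i is None:
            return np.array([len(a) for a in self.neighbors])
        return len(self.neighbors[i])

    @property
    def n_edges(self) -> int:
        return int(sum(len(a) for a in self.neighbors) // 2)

    def edge_set(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                out.add((min(i, int(j)), max(i, int(j))))
        return out

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix (n is small in this setting)."""
        a = np.zeros((self.n, self.n), dtype=bool)
        for i, nbrs in enumerate(self.neighbors):
            a[i, nbrs] = True
        return a

    def gamma_sizes(self) -> np.ndarray:
        """Self-inclusive neighborhood size |Γ_i| = deg(i) + 1 per node."""
        return self.degree() + 1

    def validate(self) -> None:
        seen = self.edge_set()
        for i, nbrs in enumerate(self.neighbors):
            if len(set(int(j) for j in nbrs)) != len(nbrs):
                raise ValueError(f"duplicate neighbor entries at node {i}")
            if i in set(int(j) for j in nbrs):
                raise ValueError(f"self-loop stored at node {i}")
        for i, j in seen:
            if i not in self.neighbors[j]:
                raise ValueError(f"asymmetric adjacency for edge ({i}, {j})")


@dataclass
class GraphSpec:
    """Declarative recipe for building a graph (JSON/YAML serializable)."""

    kind: str
    n: int
    gamma_size: int = 5
    p_e: float | None = None
    p_w: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown graph kind {self.kind!r}")
        if self.kind in (GRID, SMALLWORLD):
            side = int(round(self.n ** 0.5))
            if side * side != self.n or side < 3:
                raise ValueError(
                    f"kind={self.kind} requires n a perfect square with side >= 3, got n={self.n}"
                )
        for name in ("p_e", "p_w"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "GraphSpec":
        return cls(**json.loads(s))


def make_torus_grid(side: int) -> Graph:
    """Square torus with von-Neumann connectivity.

    Every node is adjacent to its four orthogonal neighbors with wraparound,
    so each self-inclusive neighborhood has |Γ| = 5. ``side >= 3`` is required:
    a 2x2 torus would wrap onto duplicate edges.
    """
    if side < 3:
        raise ValueError("torus grid requires side >= 3")
    n = side * side
    neighbors = []
    for i in range(n):
        r, c = divmod(i, side)
        nbrs = {
            ((r - 1) % side) * side + c,
            ((r + 1) % side) * side + c,
            r * side + (c - 1) % side,
            r * side + (c + 1) % side,
        }
        neighbors.append(np.array(sorted(nbrs), dtype=np.int64))
    return Graph(n=n, neighbors=neighbors, kind=GRID, meta={"side": side})


def make_random_graph(n: int, p_e: float, seed: int | None = None) -> Graph:
    """Erdős–Rényi graph: each of the n(n-1)/2 pairs is an edge w.p. ``p_e``."""
    if not 0.0 <= p_e <= 1.0:
        raise ValueError("p_e must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    upper = rng.random((n, n)) < p_e
    adj = np.triu(upper, k=1)
    adj = adj | adj.T
    neighbors = [np.flatnonzero(adj[i]).astype(np.int64) for i in range(n)]
    return Graph(n=n, neighbors=neighbors, kind=RANDOM, meta={"p_e": p_e, "seed": seed})


def make_smallworld(n: int, gamma_size: int = 5, p_w: float = 0.0,
                    seed: int | None = None) -> Graph:
    """Newman–Watts small world on a torus-grid substrate.

    The edge set is the union of the torus grid's edges and shortcuts: every
    unordered pair that is not a grid edge is added independently with
    probability ``p_w``. ``gamma_size`` is kept for interface symmetry; the
    substrate's self-inclusive neighborhood size is 5 (von-Neumann torus).
    """
    if gamma_size != 5:
        raise ValueError("only the von-Neumann torus substrate (gamma_size=5) is supported")
    side = int(round(n ** 0.5))
    if side * side != n:
        raise ValueError("small-world substrate requires n to be a perfect square")
    grid = make_torus_grid(side)
    if not 0.0 <= p_w <= 1.0:
        raise ValueError("p_w must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    adj = grid.adjacency()
    shortcut = np.triu(rng.random((n, n)) < p_w, k=1)
    shortcut[adj] = False  # grid edges are already present
    np.fill_diagonal(shortcut, False)
    adj = adj | shortcut | shortcut.T
    neighbors = [np.flatnonzero(adj[i]).astype(np.int64) for i in range(n)]
    return Graph(n=n, neighbors=neighbors, kind=SMALLWORLD,
                 meta={"side": side, "p_w": p_w, "seed": seed})


def neighborhood(graph: Graph, i: int, include_self: bool = True) -> np.ndarray:
    """Neighbor set Γ_i of node ``i``, optionally including ``i`` itself."""
    if not 0 <= i < graph.n:
        raise IndexError(f"node {i} out of range 0..{graph.n - 1}")
    nbrs = graph.neighbors[i]
    if include_self:
        return np.sort(np.append(nbrs, i))
    return nbrs


def make_graph(spec: GraphSpec) -> Graph:
    """Build a graph from a :class:`GraphSpec`."""
    if spec.kind == GRID:
        return make_torus_grid(int(round(spec.n ** 0.5)))
    if spec.kind == RANDOM:
        if spec.p_e is None:
            raise ValueError("random graph spec requires p_e")
        return make_random_graph(spec.n, spec.p_e, spec.seed)
    if spec.p_w is None:
        raise ValueError("small-world spec requires p_w")
    return make_smallworld(spec.n, spec.gamma_size, spec.p_w, spec.seed)


def write_edgelist_tsv(graph: Graph, path) -> None:
    """Write the edge list as TSV with 1-based node ids (header ``from\tto``)."""
    with open(path, "w") as fh:
        fh.write("from\tto\n")
        for i, j in sorted(graph.edge_set()):
            fh.write(f"{i + 1}\t{j + 1}\n")


def read_edgelist_tsv(path, n: int | None = None, kind: str = "custom") -> Graph:
    """Read a 1-based two-column edge-list TSV back into a :class:`Graph`."""
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["from", "to"]:
            raise ValueError(f"expected header 'from\\tto', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed edge row at line {lineno}: {line!r}")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            edges.append((i, j))
    if n is None:
        n = 1 + max(max(e) for e in edges) if edges else 0
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in edges:
        if i == j:
            raise ValueError(f"self-loop at node {i + 1}")
        nbrs[i].add(j)
        nbrs[j].add(i)
    neighbors = [np.array(sorted(s), dtype=np.int64) for s in nbrs]
    return Graph(n=n, neighbors=neighbors, kind=kind, meta={"source": str(path)})
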