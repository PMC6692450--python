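"""Majority-rule cellular-automaton dynamics on a graph.

Each of the ``n`` binary nodes is updated synchronously. Under the
deterministic majority rule a node becomes active exactly when more than half
of its neighborhood is active. The stochastic variant perturbs this rule: with
``r`` active neighbors out of a neighborhood of size ``|Γ|`` the node becomes
active with probability

    P(X=1 | r) = p       if r <= |Γ|/2,
                 1 - p   if r >  |Γ|/2,

so ``p`` is the probability of deviating toward activity when the majority is
inactive (and of deviating toward inactivity when the majority is active).
Ties fall in the ``p`` branch.

Two neighbor-counting conventions exist in the literature this package
follows: ``r`` may count the node itself (self-inclusive, the default here —
consistent with the mean-field maps, where |Γ| includes the node) or only the
four lattice neighbors while keeping the threshold at |Γ|/2 (the convention of
the printed 3x3 worked example). The ``include_self`` flag selects between
them explicitly; results differ in general.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .graphs import Graph

__all__ = [
    "OrbitMatrix",
    "count_active_neighbors",
    "activation_probability",
    "deterministic_step",
    "sca_step",
    "simulate",
    "counts",
    "density",
    "write_orbit_csv",
    "read_orbit_csv",
]


@dataclass
class OrbitMatrix:
    """T x n binary matrix of node states over time, with provenance."""

    states: np.ndarray
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("orbit must be a T x n matrix")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("orbit entries must be 0/1")

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def n(self) -> int:
        return self.states.shape[1]


def _check_state(graph: Graph, state) -> np.ndarray:
    state = np.asarray(state)
    if state.shape != (graph.n,):
        raise ValueError(f"state length {state.shape} does not match n={graph.n}")
    if not np.isin(state, (0, 1)).all():
        raise ValueError("state entries must be 0/1")
    return state.astype(np.int64)


def count_active_neighbors(graph: Graph, state, i: int, include_self: bool = True) -> int:
    """Number of active nodes in the (optionally self-inclusive) neighborhood of ``i``."""
    state = _check_state(graph, state)
    r = int(state[graph.neighbors[i]].sum())
    if include_self:
        r += int(state[i])
    return r


def activation_probability(r: int, gamma_size: int, p: float) -> float:
    """Probability of becoming active with ``r`` active out of ``gamma_size``."""
    if not 0 <= r <= gamma_size:
        raise ValueError(f"r={r} outside 0..{gamma_size}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return p if r <= gamma_size / 2 else 1.0 - p


def _neighbor_counts(graph: Graph, state: np.ndarray, include_self: bool) -> np.ndarray:
    r = np.array([state[nbrs].sum() for nbrs in graph.neighbors], dtype=np.int64)
    if include_self:
        r = r + state
    return r


def _gamma_sizes(graph: Graph, include_self: bool) -> np.ndarray:
    # The majority threshold is always taken against the self-inclusive
    # neighborhood size |Γ_i| = deg(i) + 1, in both counting conventions.
    return graph.degree() + 1


def deterministic_step(graph: Graph, state, include_self: bool = True) -> np.ndarray:
    """One synchronous update of the deterministic majority rule.

    Node ``i`` becomes active iff strictly more than half of its neighborhood
    size |Γ_i| is active.
    """
    state = _check_state(graph, state)
    r = _neighbor_counts(graph, state, include_self)
    gamma = _gamma_sizes(graph, include_self)
    return (r > gamma / 2).astype(np.int8)


def sca_step(graph: Graph, state, p: float, include_self: bool = True,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """One synchronous update of the stochastic majority rule.

    Each node independently becomes active with probability ``p`` if its
    active-neighbor count is at or below half its neighborhood size |Γ_i|,
    and ``1 - p`` otherwise. Each node uses its own |Γ_i| = deg(i) + 1; an
    isolated node's neighborhood is just itself, so an active isolated node
    stays active with probability ``1 - p``.
    """
    if rng is None:
        rng = np.random.default_rng()
    state = _check_state(graph, state)
    r = _neighbor_counts(graph, state, include_self)
    gamma = _gamma_sizes(graph, include_self)
    prob = np.where(r > gamma / 2, 1.0 - p, p)
    return (rng.random(graph.n) < prob).astype(np.int8)


def simulate(graph: Graph, p: float, T: int, init=None, include_self: bool = True,
             seed: int | None = None) -> OrbitMatrix:
    """Simulate the stochastic automaton for ``T`` occasions.

    ``init`` may be an explicit binary state vector or None, in which case the
    initial state is iid Bernoulli(0.5) per node. Row 0 of the orbit is the
    initial state; rows 1..T-1 are successive stochastic updates.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if init is None:
        state = (rng.random(graph.n) < 0.5).astype(np.int8)
    else:
        state = _check_state(graph, init).astype(np.int8)
    orbit = np.empty((T, graph.n), dtype=np.int8)
    orbit[0] = state
    gamma = _gamma_sizes(graph, include_self)
    half = gamma / 2.0
    nbrs = graph.neighbors
    s = state.astype(np.int64)
    for t in range(1, T):
        r = np.fromiter((s[a].sum() for a in nbrs), count=graph.n, dtype=np.int64)
        if include_self:
            r += s
        prob = np.where(r > half, 1.0 - p, p)
        s = (rng.random(graph.n) < prob).astype(np.int64)
        orbit[t] = s
    return OrbitMatrix(states=orbit, seed=seed,
                       params={"p": p, "include_self": include_self,
                               "graph_kind": graph.kind, "n": graph.n})


def counts(orbit: OrbitMatrix | np.ndarray) -> np.ndarray:
    """Active-node count Y_t per occasion (row sums)."""
    states = orbit.states if isinstance(orbit, OrbitMatrix) else np.asarray(orbit)
    return states.sum(axis=1).astype(np.int64)


def density(orbit: OrbitMatrix | np.ndarray) -> np.ndarray:
    """Density ρ_t = Y_t / n per occasion (row means)."""
    states = orbit.states if isinstance(orbit, OrbitMatrix) else np.asarray(orbit)
    return states.mean(axis=1)


def write_orbit_csv(orbit: OrbitMatrix, path) -> None:
    """Headerless 0/1 CSV (rows = occasions) plus a JSON sidecar with metadata."""
    np.savetxt(path, orbit.states, fmt="%d", delimiter=",")
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"seed": orbit.seed, "params": orbit.params}, fh, sort_keys=True)


def read_orbit_csv(path) -> OrbitMatrix:
    states = np.loadtxt(path, delimiter=",", dtype=np.int8, ndmin=2)
    seed, params = None, {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        seed, params = meta.get("seed"), meta.get("params", {})
    except FileNotFoundError:
        pass
    return OrbitMatrix(states=states, seed=seed, params=params)
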