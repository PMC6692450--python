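"""One-dimensional mean-field maps, equilibria, bifurcation diagrams.

The full automaton on a graph is reduced to a map for the expected density
ρ_t (the proportion of active nodes). Conditioning on a density ρ, the number
of active neighbors in a size-|Γ| neighborhood is Binomial(|Γ|, ρ), and the
probability that a node becomes active is the activation probability averaged
over that distribution:

    grid:        ρ' = Σ_{r=0}^{|Γ|}  P(X=1|r) C(|Γ|,r) ρ^r (1-ρ)^{|Γ|-r}
    random:      ρ' = Σ_{r=0}^{ν}    P(X=1|r) C(ν,r)   ρ^r (1-ρ)^{ν-r}
    small-world: ρ' = (|Γ|/n) grid(ρ) (1-p_w)^{n-|Γ|}
                      + ((n-|Γ|)/n) Σ_{r=|Γ|+1}^{ν} P(X=1|r) C(ν,r) ρ^r (1-ρ)^{ν-r}

with ν = ⌊p_e (n-1)⌋ (random) or ⌊p_w (n-1)⌋ (small-world) and the majority
threshold taken against the neighborhood size of each sum (|Γ| resp. ν). An
empty small-world random part (ν <= |Γ|) contributes 0; as written, the
small-world map therefore does NOT reduce to the grid map as p_w -> 0 — it
reduces to (|Γ|/n)·grid(ρ).

Iterating a map from different starting densities and keeping the tail of the
orbit yields the equilibrium set: one equilibrium (stable regime) or two
(bistable regime, "expectancy for a transition"). The parameter value
separating the two regimes is the critical point; for the symmetric grid map
with odd |Γ| it has the closed pitchfork form

    p_c = (1/2) (1 - 2^{|Γ|-1} / (|Γ| C(|Γ|-1, ⌊|Γ|/2⌋))),

7/30 ≈ 0.2333 for |Γ| = 5.

All maps accept scalar or ndarray ρ and are vectorized over ρ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "MeanFieldSpec",
    "BifurcationDiagram",
    "ClassificationResult",
    "grid_map",
    "rg_map",
    "sw_map",
    "iterate_map",
    "equilibria",
    "critical_point",
    "grid_critical_point_exact",
    "bifurcation_diagram",
    "classify",
]

# numerical defaults for equilibrium detection (iterations / kept tail /
# starting densities / merge tolerance); the map is cheap, so the iteration
# budget is generous
N_ITER_DEFAULT = 1000
TAIL_DEFAULT = 50
STARTS_DEFAULT = (0.01, 0.99)
MERGE_TOL_DEFAULT = 0.02
P_STEP_DEFAULT = 0.001
BISECT_TOL_DEFAULT = 1e-4
# convergence slows critically near the bifurcation, so the critical-point
# bisection uses a larger budget than plain equilibrium detection
N_ITER_CRITICAL = 5000


def _majority_poly(rho, p, size: int, r_min: int = 0):
    """Σ_{r=r_min}^{size} P(X=1|r) C(size,r) ρ^r (1-ρ)^{size-r}.

    Vectorized over ``rho`` and ``p`` (broadcastable shapes). The activation
    probability P(X=1|r) is ``p`` for r <= size/2 (ties included) and ``1-p``
    above.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    out = np.zeros(np.broadcast(rho, np.asarray(p, dtype=float)).shape)
    for r in range(r_min, size + 1):
        w_r = p if r <= size / 2 else 1.0 - np.asarray(p, dtype=float)
        out = out + w_r * comb(size, r) * rho ** r * (1.0 - rho) ** (size - r)
    return out


def grid_map(rho, p: float, gamma_size: int = 5):
    """Mean-field map for the torus grid with fixed neighborhood size |Γ|."""
    return _majority_poly(rho, p, gamma_size)


def nu_from_edge_prob(p_edge: float, n: int) -> int:
    """Integer part of the expected neighbor count, ν = ⌊p_edge (n-1)⌋."""
    return int(np.floor(p_edge * (n - 1)))


def rg_map(rho, p: float, p_e: float, n: int):
    """Mean-field map for the Erdős–Rényi graph; neighborhood size ν = ⌊p_e(n-1)⌋."""
    nu = nu_from_edge_prob(p_e, n)
    if nu < 1:
        raise ValueError(f"degenerate neighborhood: nu = floor(p_e*(n-1)) = {nu} < 1")
    return _majority_poly(rho, p, nu)


def sw_map(rho, p: float, p_w: float, n: int, gamma_size: int = 5):
    """Mean-field map for the Newman–Watts small world.

    Weighted combination of a grid part (no shortcut present, weight |Γ|/n)
    and a random part over the ν = ⌊p_w(n-1)⌋ expected shortcut neighborhood,
    summed from r = |Γ|+1 (the first |Γ| neighbor slots belong to the grid
    part). If ν <= |Γ| the random part is an empty sum, i.e. 0.
    """
    rho = np.asarray(rho, dtype=float)
    nu = nu_from_edge_prob(p_w, n)
    gridpart = (gamma_size / n) * grid_map(rho, p, gamma_size) * (1.0 - p_w) ** (n - gamma_size)
    if nu <= gamma_size:
        randpart = np.zeros_like(rho)
    else:
        randpart = _majority_poly(rho, p, nu, r_min=gamma_size + 1)
    return gridpart + ((n - gamma_size) / n) * randpart


@dataclass
class MeanFieldSpec:
    """Which one-dimensional map applies, and with which parameters."""

    kind: str  # {"grid", "random", "smallworld"}
    n: int
    p: float = 0.1
    gamma_size: int = 5
    p_e: float | None = None
    p_w: float | None = None

    def __post_init__(self):
        if self.kind not in ("grid", "random", "smallworld"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.kind == "random" and self.p_e is None:
            raise ValueError("random structure requires p_e")
        if self.kind == "smallworld" and self.p_w is None:
            raise ValueError("small-world structure requires p_w")

    @property
    def nu(self) -> int | None:
        if self.kind == "random":
            return nu_from_edge_prob(self.p_e, self.n)
        if self.kind == "smallworld":
            return nu_from_edge_prob(self.p_w, self.n)
        return None

    def map(self, rho, p: float | None = None):
        """Evaluate this spec's map at density ``rho`` (optionally overriding p)."""
        p = self.p if p is None else p
        if self.kind == "grid":
            return grid_map(rho, p, self.gamma_size)
        if self.kind == "random":
            return rg_map(rho, p, self.p_e, self.n)
        return sw_map(rho, p, self.p_w, self.n, self.gamma_size)

    def with_p(self, p: float) -> "MeanFieldSpec":
        return MeanFieldSpec(kind=self.kind, n=self.n, p=p,
                             gamma_size=self.gamma_size, p_e=self.p_e, p_w=self.p_w)


def iterate_map(spec: MeanFieldSpec, rho0: float, n_iter: int = N_ITER_DEFAULT) -> np.ndarray:
    """Deterministic orbit (ρ_0, ρ_1, ..., ρ_{n_iter}) of the spec's map."""
    if not 0.0 <= rho0 <= 1.0:
        raise ValueError("rho0 must lie in [0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    orbit = np.empty(n_iter + 1)
    orbit[0] = rho0
    r = rho0
    for k in range(1, n_iter + 1):
        r = float(spec.map(r))
        orbit[k] = r
    return orbit


def equilibria(spec: MeanFieldSpec, n_iter: int = N_ITER_DEFAULT, tail: int = TAIL_DEFAULT,
               starts=STARTS_DEFAULT, tol: float = MERGE_TOL_DEFAULT) -> list[float]:
    """Limiting densities of the map from several starting points.

    Each start is iterated ``n_iter`` times; the mean of the last ``tail``
    values is its limit. Limits closer than ``tol`` are merged. A tail that
    has not settled (spread > tol within one start) raises rather than being
    silently merged.
    """
    limits = []
    for rho0 in starts:
        orbit = iterate_map(spec, rho0, n_iter)
        tail_vals = orbit[-tail:]
        if tail_vals.max() - tail_vals.min() > tol:
            raise RuntimeError(
                f"non-convergent orbit from rho0={rho0} (tail spread "
                f"{tail_vals.max() - tail_vals.min():.4f} > tol={tol})"
            )
        limits.append(float(tail_vals.mean()))
    merged: list[float] = []
    for v in sorted(limits):
        if merged and abs(v - merged[-1]) <= tol:
            merged[-1] = (merged[-1] + v) / 2.0
        else:
            merged.append(v)
    return merged


def _limits_batch(spec: MeanFieldSpec, p_values: np.ndarray, n_iter: int,
                  tail: int = TAIL_DEFAULT, starts=STARTS_DEFAULT) -> np.ndarray:
    """Tail-mean limits, shape (len(p_values), len(starts)).

    Iterates all (p, start) orbits simultaneously; the maps are vectorized
    over both ρ and p, so the whole bifurcation scan is a handful of array
    operations per iteration.
    """
    p_col = np.asarray(p_values, dtype=float)[:, None]
    rho = np.tile(np.asarray(starts, dtype=float), (len(p_values), 1))
    acc = np.zeros_like(rho)
    for k in range(n_iter):
        rho = spec.map(rho, p=p_col)
        if k >= n_iter - tail:
            acc += rho
    return acc / tail


def _n_equilibria(spec: MeanFieldSpec, p: float, n_iter: int) -> int:
    return len(equilibria(spec.with_p(p), n_iter=n_iter))


def grid_critical_point_exact(gamma_size: int = 5) -> float:
    """Closed-form pitchfork critical point of the grid map (odd |Γ|).

    The symmetric fixed point ρ = 1/2 loses stability when (1-2p) g'(1/2)
    passes 1, where g is the majority tail probability; solving gives
    p_c = (1/2)(1 - 2^{|Γ|-1} / (|Γ| C(|Γ|-1, ⌊|Γ|/2⌋))).
    """
    return 0.5 * (1.0 - 2 ** (gamma_size - 1) / (gamma_size * comb(gamma_size - 1, gamma_size // 2)))


_CP_CACHE: dict[tuple, float | None] = {}


def critical_point(spec: MeanFieldSpec, p_lo: float = 1e-3, p_hi: float = 0.5,
                   coarse_step: float = P_STEP_DEFAULT, tol: float = BISECT_TOL_DEFAULT,
                   n_iter: int = N_ITER_CRITICAL) -> float | None:
    """Largest p below which the map has two equilibria, or None if never bistable.

    A coarse scan brackets the change in equilibrium count, then bisection
    refines it to ``tol``. The boundary itself is assigned to the stable side.
    The result is deterministic in the spec's structural parameters (p itself
    plays no role), so it is memoized.
    """
    key = (spec.kind, spec.n, spec.gamma_size, spec.p_e, spec.p_w,
           p_lo, p_hi, coarse_step, tol, n_iter)
    if key in _CP_CACHE:
        return _CP_CACHE[key]
    grid_p = np.arange(p_lo, p_hi + coarse_step / 2, coarse_step)
    limits = _limits_batch(spec, grid_p, n_iter)
    bistable = (limits[:, -1] - limits[:, 0]) > MERGE_TOL_DEFAULT
    if not bistable.any():
        _CP_CACHE[key] = None
        return None
    last = int(np.flatnonzero(bistable).max())
    lo = float(grid_p[last])
    hi = float(grid_p[last + 1]) if last + 1 < len(grid_p) else p_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _n_equilibria(spec, mid, n_iter) >= 2:
            lo = mid
        else:
            hi = mid
    _CP_CACHE[key] = 0.5 * (lo + hi)
    return _CP_CACHE[key]


@dataclass
class BifurcationDiagram:
    p_values: np.ndarray
    equilibria: list[list[float]]
    critical_point: float | None = None
    spec: MeanFieldSpec | None = None

    def to_long_rows(self):
        """(p, equilibrium_value) rows for CSV export."""
        return [(float(p), float(v)) for p, eqs in zip(self.p_values, self.equilibria)
                for v in eqs]


def bifurcation_diagram(spec: MeanFieldSpec, p_values=None,
                        n_iter: int = N_ITER_DEFAULT, refine: bool = True) -> BifurcationDiagram:
    """Equilibrium set of the map over a grid of p values in (0, 0.5]."""
    if p_values is None:
        p_values = np.arange(P_STEP_DEFAULT, 0.5 + P_STEP_DEFAULT / 2, P_STEP_DEFAULT)
    p_values = np.asarray(p_values, dtype=float)
    if np.any((p_values <= 0) | (p_values > 0.5)):
        raise ValueError("p grid must lie in (0, 0.5]")
    limits = _limits_batch(spec, p_values, n_iter)
    eqs = []
    for row in limits:
        merged: list[float] = []
        for v in sorted(float(x) for x in row):
            if merged and abs(v - merged[-1]) <= MERGE_TOL_DEFAULT:
                merged[-1] = (merged[-1] + v) / 2.0
            else:
                merged.append(v)
        eqs.append(merged)
    cp = critical_point(spec) if refine else None
    return BifurcationDiagram(p_values=p_values, equilibria=eqs,
                              critical_point=cp, spec=spec)


@dataclass
class ClassificationResult:
    """Stable-vs-bistable verdict for a fitted individual."""

    p_hat: float
    equilibria_at_p_hat: list[float]
    critical_point: float | None
    verdict: str = field(init=False)  # {"bistable", "stable"}

    def __post_init__(self):
        self.verdict = "bistable" if len(self.equilibria_at_p_hat) == 2 else "stable"

    @property
    def transition_expectancy(self) -> bool:
        return self.verdict == "bistable"


def classify(spec: MeanFieldSpec, p_hat: float | None = None,
             with_critical_point: bool = True) -> ClassificationResult:
    """Classify an individual's transition expectancy at the fitted p.

    The verdict consults the equilibrium set at p̂ directly (bistable iff two
    equilibria), which stays correct even for maps whose bistable region is
    not a simple interval. An estimate exactly at the critical point is
    classified stable (the equilibrium count there is one).
    """
    p_hat = spec.p if p_hat is None else p_hat
    if not 0.0 < p_hat <= 0.5:
        raise ValueError(
            f"p_hat={p_hat} outside (0, 0.5]; by the p <-> 1-p symmetry of the "
            "activation rule, refit with the bounded (0, 0.5] parameterization"
        )
    eqs = equilibria(spec.with_p(p_hat), n_iter=N_ITER_CRITICAL)
    cp = critical_point(spec) if with_critical_point else None
    return ClassificationResult(p_hat=p_hat, equilibria_at_p_hat=eqs, critical_point=cp)
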