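"""Maximum-likelihood estimation of the noise parameter p (and graph parameters).

The count series Y_t (number of active nodes) is modeled as a Markov chain
with binomial transitions: given Y_t = x_t, the next count is

    Y_{t+1} | Y_t = x_t  ~  Binomial(n, ρ'(x_t / n)),

where ρ' is the mean-field map of the assumed graph structure. The total
log-likelihood of a length-T series is the sum of the T-1 transition log
probabilities; no ergodicity is assumed, so no stationary simplification is
applied.

Estimation maximizes this log-likelihood over p (bounded to (0, 0.5] by
default — the activation rule is symmetric under p -> 1-p combined with state
relabeling, and the bifurcation interpretation lives on (0, 0.5]). For the
random and small-world structures the graph parameter is estimated jointly.
The likelihood depends on the edge/wiring probability only through the
integer expected-neighborhood size ν = ⌊p_edge (n-1)⌋ (plus, for the small
world, a smooth (1-p_w)^{n-|Γ|} factor), so the maximization profiles over
the ν bins exactly: within each bin the remaining parameters are continuous
and a bounded optimizer plus a dense grid on p finds the maximum; the best
bin wins. The reported p̂(e)/p̂(w) is the midpoint of the winning bin.

Standard errors come from the central-finite-difference Hessian of the
negative log-likelihood at the optimum (inverse Hessian diagonal). A
paper-literal mode additionally scales the inverse by 1/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .meanfield import MeanFieldSpec

__all__ = [
    "FitResult",
    "ModelComparison",
    "transition_logprob",
    "loglik",
    "fit",
    "standard_errors",
    "information_criteria",
    "select_model",
    "simulate_chain",
]

PROB_EPS = 1e-12      # clamp for the binomial success probability
P_BOUND_DEFAULT = 0.5  # upper estimation bound for p
P_LOWER = 1e-6
GRID_STEP = 0.001      # dense refinement grid on the p axis
P_STARTS = (0.05, 0.15, 0.25, 0.35, 0.45)


class NeedsVarianceError(ValueError):
    """Raised when a count series is constant and the likelihood is uninformative."""


class NonConvergenceError(RuntimeError):
    """Raised when every optimization start fails; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class FitResult:
    structure: str
    n: int
    T: int
    p_hat: float
    loglik: float
    graph_param_hat: float | None = None
    nu_hat: int | None = None
    se_p: float | None = None
    se_graph_param: float | None = None
    se_note: str | None = None
    bic: float = field(init=False)
    aic: float = field(init=False)
    k: int = field(init=False)
    converged: bool = True
    n_starts: int = 0
    gamma_size: int = 5

    def __post_init__(self):
        self.k = 1 if self.structure == "grid" else 2
        n_trans = self.T - 1
        self.bic = self.k * np.log(n_trans) - 2.0 * self.loglik
        self.aic = 2.0 * self.k - 2.0 * self.loglik

    def spec(self) -> MeanFieldSpec:
        """Mean-field spec at the fitted parameters."""
        return MeanFieldSpec(
            kind=self.structure, n=self.n, p=self.p_hat, gamma_size=self.gamma_size,
            p_e=self.graph_param_hat if self.structure == "random" else None,
            p_w=self.graph_param_hat if self.structure == "smallworld" else None,
        )

    def to_dict(self) -> dict:
        return {
            "structure": self.structure, "n": self.n, "T": self.T,
            "p_hat": self.p_hat, "graph_param_hat": self.graph_param_hat,
            "nu_hat": self.nu_hat, "loglik": self.loglik,
            "se_p": self.se_p, "se_graph_param": self.se_graph_param,
            "se_note": self.se_note, "bic": self.bic, "aic": self.aic,
            "k": self.k, "converged": self.converged, "gamma_size": self.gamma_size,
        }


@dataclass
class ModelComparison:
    fits: dict[str, FitResult]
    selected: str = field(init=False)

    def __post_init__(self):
        self.selected = min(self.fits, key=lambda s: self.fits[s].bic)

    @property
    def best(self) -> FitResult:
        return self.fits[self.selected]


def _validate_counts(x, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D series")
    if np.any((x < 0) | (x > n)) or not np.issubdtype(x.dtype, np.number):
        raise ValueError(f"counts must lie in 0..{n}")
    return x.astype(np.int64)


def _clamped_map(spec: MeanFieldSpec, rho, p=None):
    return np.clip(spec.map(rho, p=p), PROB_EPS, 1.0 - PROB_EPS)


def transition_logprob(x_t: int, x_next: int, n: int, spec: MeanFieldSpec) -> float:
    """Log probability of going from ``x_t`` to ``x_next`` active nodes."""
    for v in (x_t, x_next):
        if not 0 <= v <= n:
            raise ValueError(f"count {v} outside 0..{n}")
    rho_next = _clamped_map(spec, x_t / n)
    return float(stats.binom.logpmf(x_next, n, rho_next))


def loglik(counts, spec: MeanFieldSpec, n: int | None = None) -> float:
    """Total log-likelihood of a count series under the spec's binomial chain."""
    n = spec.n if n is None else n
    x = _validate_counts(counts, n)
    if len(x) < 2:
        raise ValueError("need at least two occasions (one transition)")
    rho_next = _clamped_map(spec, x[:-1] / n)
    return float(stats.binom.logpmf(x[1:], n, rho_next).sum())


class _TransitionTable:
    """Aggregated (x_t, x_{t+1}) transition counts for fast repeated evaluation.

    The likelihood depends on the data only through how often each transition
    pair occurs, so a series of length T collapses to at most (n+1)^2 weighted
    pairs (usually far fewer).
    """

    def __init__(self, counts, n: int):
        x = _validate_counts(counts, n)
        if len(x) < 2:
            raise ValueError("need at least two occasions (one transition)")
        self.n = n
        codes = x[:-1] * (n + 1) + x[1:]
        uniq, cnt = np.unique(codes, return_counts=True)
        self.x_from = (uniq // (n + 1)).astype(np.int64)
        self.x_to = (uniq % (n + 1)).astype(np.int64)
        self.weight = cnt.astype(np.float64)
        # binomial coefficient part of the pmf is p-independent
        self._log_binom = (
            stats.binom.logpmf(self.x_to, n, 0.5) + n * np.log(2.0)
        )

    def loglik(self, spec: MeanFieldSpec, p=None) -> float:
        rho = _clamped_map(spec, self.x_from / self.n, p=p)
        ll = (self._log_binom + self.x_to * np.log(rho)
              + (self.n - self.x_to) * np.log1p(-rho))
        return float(np.dot(self.weight, ll))

    def loglik_grid(self, spec: MeanFieldSpec, p_grid: np.ndarray) -> np.ndarray:
        """Vectorized log-likelihood over a grid of p values."""
        rho = _clamped_map(spec, self.x_from[None, :] / self.n, p=np.asarray(p_grid)[:, None])
        ll = (self._log_binom[None, :] + self.x_to[None, :] * np.log(rho)
              + (self.n - self.x_to[None, :]) * np.log1p(-rho))
        return ll @ self.weight


def _maximize_p(table: _TransitionTable, spec: MeanFieldSpec,
                p_max: float) -> tuple[float, float]:
    """Best p for a fixed structure/graph parameter: dense grid + local polish.

    The dense 0.001-step grid guards against the near-flat likelihood when
    the series hovers at density 0.5 (where the map barely depends on p);
    bounded scalar optimization then polishes the best grid point.
    """
    p_grid = np.arange(GRID_STEP, p_max + GRID_STEP / 2, GRID_STEP)
    ll = table.loglik_grid(spec, p_grid)
    i = int(np.argmax(ll))
    lo = max(P_LOWER, p_grid[i] - GRID_STEP)
    hi = min(p_max, p_grid[i] + GRID_STEP)
    res = optimize.minimize_scalar(lambda p: -table.loglik(spec, p=p),
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-7})
    best_p, best_ll = float(p_grid[i]), float(ll[i])
    if res.success and -res.fun >= best_ll:
        best_p, best_ll = float(res.x), float(-res.fun)
    # multi-start local optimization over the full range as a safety net
    for p0 in P_STARTS:
        if p0 > p_max:
            continue
        r = optimize.minimize(lambda q: -table.loglik(spec, p=float(q[0])),
                              x0=[p0], bounds=[(P_LOWER, p_max)], method="L-BFGS-B")
        if r.success and -r.fun > best_ll:
            best_p, best_ll = float(r.x[0]), float(-r.fun)
    return best_p, best_ll


def fit(counts, structure: str, n: int, gamma_size: int = 5,
        p_max: float = P_BOUND_DEFAULT) -> FitResult:
    """Maximum-likelihood fit of p (and graph parameter) for one structure.

    ``p_max`` may be raised to ``1 - 1e-6`` for diagnostics; the default keeps
    p on (0, 0.5], the interval on which the bifurcation analysis is read.
    """
    x = _validate_counts(counts, n)
    if np.all(x == x[0]):
        raise NeedsVarianceError(
            "count series is constant; the likelihood carries no information "
            "about p (mirrors the variance exclusion rule)"
        )
    table = _TransitionTable(x, n)
    T = len(x)

    if structure == "grid":
        spec = MeanFieldSpec(kind="grid", n=n, p=0.1, gamma_size=gamma_size)
        p_hat, ll = _maximize_p(table, spec, p_max)
        res = FitResult(structure="grid", n=n, T=T, p_hat=p_hat, loglik=ll,
                        gamma_size=gamma_size, n_starts=len(P_STARTS) + 1)
        se_p, se_g, note = standard_errors(res, x)
        res.se_p, res.se_graph_param, res.se_note = se_p, se_g, note
        return res

    if structure == "random":
        best = None
        for nu in range(1, n):
            spec = MeanFieldSpec(kind="random", n=n, p=0.1, p_e=(nu + 0.5) / (n - 1))
            p_hat, ll = _maximize_p(table, spec, p_max)
            if best is None or ll > best[2]:
                best = (nu, p_hat, ll)
        nu, p_hat, ll = best
        res = FitResult(structure="random", n=n, T=T, p_hat=p_hat, loglik=ll,
                        graph_param_hat=(nu + 0.5) / (n - 1), nu_hat=nu,
                        gamma_size=gamma_size, n_starts=n - 1)
        se_p, se_g, note = standard_errors(res, x)
        res.se_p, res.se_graph_param, res.se_note = se_p, se_g, note
        return res

    if structure == "smallworld":
        best = None
        diagnostics = []
        for nu in range(0, n):
            b_lo = max(P_LOWER, nu / (n - 1))
            b_hi = min(1.0 - P_LOWER, (nu + 1) / (n - 1) - 1e-9)
            if b_lo >= b_hi:
                continue
            pw0 = 0.5 * (b_lo + b_hi)

            def negll(theta):
                p, pw = theta
                spec = MeanFieldSpec(kind="smallworld", n=n, p=0.1,
                                     gamma_size=gamma_size, p_w=float(pw))
                return -table.loglik(spec, p=float(p))

            for p0 in (0.1, 0.3):
                r = optimize.minimize(negll, x0=[p0, pw0],
                                      bounds=[(P_LOWER, p_max), (b_lo, b_hi)],
                                      method="L-BFGS-B")
                if not r.success:
                    diagnostics.append((nu, p0, r.message))
                    continue
                if best is None or -r.fun > best[3]:
                    best = (nu, float(r.x[0]), float(r.x[1]), float(-r.fun))
            # dense p grid at the bin-midpoint wiring probability
            spec_mid = MeanFieldSpec(kind="smallworld", n=n, p=0.1,
                                     gamma_size=gamma_size, p_w=pw0)
            p_hat, ll = _maximize_p(table, spec_mid, p_max)
            if best is None or ll > best[3]:
                best = (nu, p_hat, pw0, ll)
        if best is None:
            raise NonConvergenceError("no small-world optimization start converged",
                                      diagnostics)
        nu, p_hat, pw_hat, ll = best
        res = FitResult(structure="smallworld", n=n, T=T, p_hat=p_hat, loglik=ll,
                        graph_param_hat=pw_hat, nu_hat=nu,
                        gamma_size=gamma_size, n_starts=2 * n)
        se_p, se_g, note = standard_errors(res, x)
        res.se_p, res.se_graph_param, res.se_note = se_p, se_g, note
        return res

    raise ValueError(f"unknown structure {structure!r}")


def _negloglik_at(theta: np.ndarray, res: FitResult, table: _TransitionTable) -> float:
    p = float(theta[0])
    p = min(max(p, PROB_EPS), 1.0 - PROB_EPS)
    if res.structure == "grid":
        spec = MeanFieldSpec(kind="grid", n=res.n, p=p, gamma_size=res.gamma_size)
    elif res.structure == "random":
        spec = MeanFieldSpec(kind="random", n=res.n, p=p, p_e=float(theta[1]))
    else:
        spec = MeanFieldSpec(kind="smallworld", n=res.n, p=p,
                             gamma_size=res.gamma_size, p_w=float(theta[1]))
    return -table.loglik(spec)


def _fd_hessian(f, theta: np.ndarray) -> np.ndarray:
    """Central-finite-difference Hessian with relative steps max(1e-4, 1e-4|θ|)."""
    k = len(theta)
    h = np.maximum(1e-4, 1e-4 * np.abs(theta))
    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def standard_errors(fit_result: FitResult, counts, mode: str = "default"):
    """(se_p, se_graph_param, note) from the observed-information Hessian.

    ``mode="default"``: SE = sqrt of the inverse-Hessian diagonal of the total
    negative log-likelihood (the usual observed-information SE).
    ``mode="paper"``: the inverse is additionally scaled by 1/T.

    For the random structure the likelihood is flat in p(e) within a ν bin,
    so its curvature is zero: the SE for the graph parameter is reported as
    unavailable and the p SE falls back to the scalar curvature in p.
    """
    if mode not in ("default", "paper"):
        raise ValueError("mode must be 'default' or 'paper'")
    x = _validate_counts(counts, fit_result.n)
    table = _TransitionTable(x, fit_result.n)
    scale = 1.0 / len(x) if mode == "paper" else 1.0

    if fit_result.structure == "grid":
        theta = np.array([fit_result.p_hat])
    else:
        theta = np.array([fit_result.p_hat, fit_result.graph_param_hat])
    H = _fd_hessian(lambda th: _negloglik_at(th, fit_result, table), theta)

    def _scalar_se(h: float) -> float | None:
        return float(np.sqrt(scale / h)) if h > 0 else None

    if len(theta) == 1:
        se = _scalar_se(H[0, 0])
        return se, None, None if se is not None else "non-positive curvature at optimum"
    # joint (p, graph parameter) case
    try:
        cov = np.linalg.inv(H) * scale
        diag = np.diag(cov)
        if np.all(diag > 0):
            return float(np.sqrt(diag[0])), float(np.sqrt(diag[1])), None
    except np.linalg.LinAlgError:
        pass
    # graph-parameter direction flat (piecewise-constant in nu) or boundary:
    # fall back to the profile curvature in p alone
    se_p = _scalar_se(H[0, 0])
    note = ("graph-parameter SE unavailable: likelihood locally flat or "
            "Hessian not positive definite")
    return se_p, None, note


def information_criteria(fit_result: FitResult) -> tuple[float, float]:
    """(BIC, AIC); BIC uses the number of transitions T-1 as the sample size."""
    return fit_result.bic, fit_result.aic


def select_model(counts, n: int, gamma_size: int = 5,
                 p_max: float = P_BOUND_DEFAULT) -> ModelComparison:
    """Fit all three structures and select the lowest-BIC model."""
    fits = {s: fit(counts, s, n, gamma_size=gamma_size, p_max=p_max)
            for s in ("grid", "random", "smallworld")}
    return ModelComparison(fits=fits)


def simulate_chain(spec: MeanFieldSpec, T: int, x0: int | None = None,
                   seed: int | None = None) -> np.ndarray:
    """Simulate the binomial Markov chain itself (the correctly specified model).

    ``x0`` defaults to a Binomial(n, 0.5) draw. Returns a length-T integer
    count series.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    n = spec.n
    x = np.empty(T, dtype=np.int64)
    x[0] = rng.binomial(n, 0.5) if x0 is None else int(x0)
    if not 0 <= x[0] <= n:
        raise ValueError(f"x0 outside 0..{n}")
    for t in range(1, T):
        rho = float(_clamped_map(spec, x[t - 1] / n))
        x[t] = rng.binomial(n, rho)
    return x
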