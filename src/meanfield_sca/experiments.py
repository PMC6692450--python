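"""Simulation studies and the synthetic fixture generator.

The empirical datasets behind this method cannot be redistributed, so study
inputs are generated by the automaton itself: a graph is built per condition,
the stochastic majority-rule dynamics are simulated, and the ground-truth
parameters are carried alongside the orbit. The study runners reproduce the
numerical designs used to validate the estimator:

* ``error_study`` — mean absolute estimation error Δ̄(p) = mean |p̂ - p| (and
  the analogues for the graph parameters), plus SD of p̂ and mean SE, under
  the correctly specified structure;
* ``misspecification_study`` — every simulated dataset is fitted under all
  three structures; Δ̄(p) per (true, fitted) pair and BIC selection rates;
* ``subset_study`` — refit on a random chronological subset (50% or 75%) of
  the occasions and report verdict agreement with the full-data verdict;
  retained occasions are treated as adjacent transitions;
* ``agreement`` — raw agreement share and Cohen's κ between two binary
  verdict vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import inference
from .automaton import OrbitMatrix, counts as orbit_counts, simulate
from .graphs import GraphSpec, make_graph
from .meanfield import MeanFieldSpec, classify

__all__ = [
    "Condition",
    "StudyResult",
    "generate_fixture",
    "write_fixture",
    "read_fixture",
    "error_study",
    "misspecification_study",
    "subset_study",
    "agreement",
]


@dataclass
class Condition:
    """One cell of a simulation design."""

    structure: str
    n: int
    T: int
    p: float
    p_e: float | None = None
    p_w: float | None = None
    replications: int = 100
    seed: int = 0
    gamma_size: int = 5

    def __post_init__(self):
        if self.structure not in ("grid", "random", "smallworld"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "random" and self.p_e is None:
            raise ValueError("random condition requires p_e")
        if self.structure == "smallworld" and self.p_w is None:
            raise ValueError("small-world condition requires p_w")

    def graph_spec(self, seed: int) -> GraphSpec:
        return GraphSpec(kind=self.structure, n=self.n, gamma_size=self.gamma_size,
                         p_e=self.p_e, p_w=self.p_w, seed=seed)

    def graph_param(self) -> float | None:
        return self.p_e if self.structure == "random" else self.p_w


@dataclass
class StudyResult:
    """Tidy per-condition summaries; ``rows`` holds one record per replication."""

    kind: str
    summaries: list[dict] = field(default_factory=list)
    rows: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "summaries": self.summaries,
                           "failures": self.failures}, indent=2, default=float)


def _spawn_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(k) % (2 ** 31)]


def generate_fixture(condition: Condition, seed: int) -> tuple[OrbitMatrix, dict]:
    """Simulate one dataset for a condition; returns (orbit, truth record).

    A fresh graph is drawn per fixture for the random families. The truth
    record carries everything needed to reproduce the fixture bit for bit.
    """
    graph_seed, sim_seed = _spawn_seeds(seed, 2)
    graph = make_graph(condition.graph_spec(graph_seed))
    orbit = simulate(graph, condition.p, condition.T, seed=sim_seed)
    truth = {"structure": condition.structure, "n": condition.n, "T": condition.T,
             "p": condition.p, "p_e": condition.p_e, "p_w": condition.p_w,
             "gamma_size": condition.gamma_size,
             "graph_seed": graph_seed, "sim_seed": sim_seed, "seed": seed}
    return orbit, truth


def write_fixture(orbit: OrbitMatrix, truth: dict, path) -> None:
    """Serialize orbit (headerless 0/1 CSV) plus truth record (JSON sidecar)."""
    np.savetxt(path, orbit.states, fmt="%d", delimiter=",")
    with open(str(path) + ".truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True)


def read_fixture(path) -> tuple[OrbitMatrix, dict]:
    states = np.loadtxt(path, delimiter=",", dtype=np.int8, ndmin=2)
    with open(str(path) + ".truth.json") as fh:
        truth = json.load(fh)
    return OrbitMatrix(states=states, seed=truth.get("sim_seed"), params=truth), truth


def _fit_counts(y: np.ndarray, structure: str, n: int, gamma_size: int):
    """Fit, translating degenerate series into a recorded failure."""
    return inference.fit(y, structure, n, gamma_size=gamma_size)


def error_study(conditions: list[Condition]) -> StudyResult:
    """Parameter recovery under the correctly specified structure."""
    result = StudyResult(kind="error")
    for cond in conditions:
        seeds = _spawn_seeds(cond.seed, cond.replications)
        p_hats, errs, ses, graph_errs = [], [], [], []
        for rep, s in enumerate(seeds):
            orbit, truth = generate_fixture(cond, s)
            y = orbit_counts(orbit)
            try:
                fr = _fit_counts(y, cond.structure, cond.n, cond.gamma_size)
            except (inference.NeedsVarianceError, inference.NonConvergenceError) as e:
                result.failures.append({"condition": asdict(cond), "rep": rep,
                                        "error": str(e)})
                continue
            p_hats.append(fr.p_hat)
            errs.append(abs(fr.p_hat - cond.p))
            if fr.se_p is not None:
                ses.append(fr.se_p)
            true_gp = cond.graph_param()
            if true_gp is not None and fr.graph_param_hat is not None:
                graph_errs.append(abs(fr.graph_param_hat - true_gp))
            result.rows.append({"condition": asdict(cond), "rep": rep,
                                "p_hat": fr.p_hat, "graph_param_hat": fr.graph_param_hat,
                                "se_p": fr.se_p, "loglik": fr.loglik})
        summary = {
            "condition": asdict(cond),
            "n_fitted": len(p_hats),
            "delta_p": float(np.mean(errs)) if errs else None,
            "sd_p_hat": float(np.std(p_hats, ddof=1)) if len(p_hats) > 1 else None,
            "mean_se": float(np.mean(ses)) if ses else None,
            "delta_graph_param": float(np.mean(graph_errs)) if graph_errs else None,
        }
        if summary["sd_p_hat"] is not None and summary["mean_se"] is not None:
            summary["abs_sd_minus_se"] = abs(summary["sd_p_hat"] - summary["mean_se"])
        result.summaries.append(summary)
    return result


def misspecification_study(conditions: list[Condition],
                           gamma_size: int = 5) -> StudyResult:
    """Fit every simulated dataset under all three structures; BIC selection rates."""
    structures = ("grid", "random", "smallworld")
    result = StudyResult(kind="misspecification")
    for cond in conditions:
        seeds = _spawn_seeds(cond.seed, cond.replications)
        errs = {s: [] for s in structures}
        selected = {s: 0 for s in structures}
        n_ok = 0
        for rep, s in enumerate(seeds):
            orbit, truth = generate_fixture(cond, s)
            y = orbit_counts(orbit)
            fits = {}
            try:
                for st in structures:
                    fits[st] = _fit_counts(y, st, cond.n, gamma_size)
            except (inference.NeedsVarianceError, inference.NonConvergenceError) as e:
                result.failures.append({"condition": asdict(cond), "rep": rep,
                                        "error": str(e)})
                continue
            n_ok += 1
            best = min(fits, key=lambda st: fits[st].bic)
            selected[best] += 1
            for st in structures:
                errs[st].append(abs(fits[st].p_hat - cond.p))
            result.rows.append({"condition": asdict(cond), "rep": rep,
                                "selected": best,
                                **{f"p_hat_{st}": fits[st].p_hat for st in structures},
                                **{f"bic_{st}": fits[st].bic for st in structures}})
        result.summaries.append({
            "condition": asdict(cond), "n_fitted": n_ok,
            "delta_p_by_fit": {st: (float(np.mean(v)) if v else None)
                               for st, v in errs.items()},
            "bic_selection_rate": {st: (selected[st] / n_ok if n_ok else None)
                                   for st in structures},
        })
    return result


def subset_study(conditions: list[Condition], fraction: float = 0.75,
                 repeats: int = 100, min_T: int = 5) -> StudyResult:
    """Verdict stability under chronological subsampling of occasions.

    For each condition one dataset is generated and classified on the full
    series; then ``repeats`` random subsets of the stated fraction of
    occasions (chronological order preserved, retained points treated as
    adjacent transitions) are refitted and reclassified. The summary reports
    the share of subsets whose stable/bistable verdict agrees with the
    full-data verdict.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    result = StudyResult(kind="subset")
    for cond in conditions:
        seeds = _spawn_seeds(cond.seed, repeats + 1)
        orbit, truth = generate_fixture(cond, seeds[0])
        y = orbit_counts(orbit)
        fr_full = _fit_counts(y, cond.structure, cond.n, cond.gamma_size)
        full_verdict = classify(fr_full.spec(), with_critical_point=False).verdict
        agree, n_ok = 0, 0
        for rep in range(repeats):
            rng = np.random.default_rng(seeds[rep + 1])
            keep = max(min_T, int(round(fraction * cond.T)))
            if keep < min_T:
                result.failures.append({"condition": asdict(cond), "rep": rep,
                                        "error": "subset below minimum length"})
                continue
            idx = np.sort(rng.choice(cond.T, size=keep, replace=False))
            try:
                fr = _fit_counts(y[idx], cond.structure, cond.n, cond.gamma_size)
            except (inference.NeedsVarianceError, inference.NonConvergenceError) as e:
                result.failures.append({"condition": asdict(cond), "rep": rep,
                                        "error": str(e)})
                continue
            verdict = classify(fr.spec(), with_critical_point=False).verdict
            n_ok += 1
            agree += int(verdict == full_verdict)
            result.rows.append({"condition": asdict(cond), "rep": rep,
                                "subset_T": keep, "p_hat": fr.p_hat,
                                "verdict": verdict, "full_verdict": full_verdict})
        result.summaries.append({
            "condition": asdict(cond), "fraction": fraction, "n_ok": n_ok,
            "full_verdict": full_verdict,
            "verdict_agreement": agree / n_ok if n_ok else None,
        })
    return result


def agreement(verdicts_a, verdicts_b) -> tuple[float, float | None]:
    """(raw agreement share, Cohen's κ) between two binary verdict vectors.

    κ = (p_o - p_c) / (1 - p_c) with chance agreement p_c from the marginal
    products. κ is None (undefined) when p_c = 1, i.e. both raters are
    constant and identical in marginals.
    """
    a = np.asarray(verdicts_a).astype(int)
    b = np.asarray(verdicts_b).astype(int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("verdict vectors must be equal-length 1-D")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("verdicts must be binary")
    p_o = float(np.mean(a == b))
    pa1, pb1 = a.mean(), b.mean()
    p_c = float(pa1 * pb1 + (1 - pa1) * (1 - pb1))
    if p_c == 1.0:
        return p_o, None
    return p_o, float((p_o - p_c) / (1.0 - p_c))
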