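# Methods

This note documents the model, the numerical choices, and the limits of what
the package's tests demonstrate.

## Model and assumptions

A stochastic cellular automaton (SCA) on an undirected graph of `n` binary
nodes is updated synchronously by the noisy majority rule: a node with `r`
active nodes in its self-inclusive neighborhood of size `|Γ|` becomes active
with probability `p` when `r ≤ |Γ|/2` and `1 − p` otherwise. Ties fall in
the `p` branch. The mean-field reduction assumes (1) a common effective
neighborhood size, (2) binary node states, and (3) exchangeable node
behavior; under these, conditioning on the density ρ_t makes the active
count of a neighborhood Binomial(|Γ|, ρ_t), and the expected density evolves
by the one-dimensional maps implemented in `meanfield.py` (grid, random
graph with ν = ⌊p_e(n−1)⌋, Newman–Watts small world).

**Neighbor-counting conventions.** The mean-field sums run over the
self-inclusive neighborhood, so the simulator's default is `include_self =
True` (the node's own state counts toward `r`, and the threshold is
|Γ_i|/2 with |Γ_i| = deg(i) + 1). The classic printed 3×3 worked example
instead counts only the four lattice neighbors while keeping the threshold
at |Γ|/2 = 2.5; `include_self = False` reproduces that convention. The two
conventions genuinely differ, so the flag is explicit and never inferred.

**Heterogeneous degrees.** On random and small-world graphs each node uses
its own |Γ_i|. An isolated node's neighborhood is just itself; when active
it stays active with probability 1 − p.

**Small-world map.** The wiring parameter enters twice: through
ν = ⌊p_w(n−1)⌋ in the shortcut sum (which starts at r = |Γ|+1 and is empty
when ν ≤ |Γ|) and through the smooth no-shortcut factor (1−p_w)^{n−|Γ|}.
As written the map does **not** reduce to the grid map at p_w → 0 — it
reduces to (|Γ|/n)·grid(ρ). This is faithful to the two-part weighting as
specified; users comparing structures should be aware that the small-world
map can take very small values for sparse wiring, which is also why the
small-world fit rarely wins the BIC comparison on grid-generated data.

## Estimation

The count series is a Markov chain with binomial transitions whose success
probability is the mean-field map evaluated at the previous density; the
total log-likelihood is the sum over the T−1 transitions (no ergodicity
assumption, no stationary simplification). Numerical choices:

* Success probabilities are clamped to [1e−12, 1−1e−12] before logs.
* p is estimated on (0, 0.5] by default. The activation rule is invariant
  under p → 1−p combined with relabeling the states, and the bifurcation
  diagram is read on (0, 0.5]; the full-range option exists for diagnostics.
* The likelihood depends on the data only through the aggregated transition
  pair counts, which makes repeated evaluation cheap (at most (n+1)² terms).
* **Grid structure:** dense 0.001-step grid on p, bounded scalar polish of
  the best grid point, plus multi-start L-BFGS-B from p ∈ {0.05,…,0.45} as a
  safety net; the best candidate wins. The dense grid guards against the
  near-flat likelihood when the series hovers at density 0.5, where the map
  barely depends on p — the regime with the largest estimation errors.
* **Random structure:** the likelihood is piecewise constant in p_e (it
  enters only through the integer ν), so a continuous 2-D optimizer is
  unreliable; the fit instead profiles exactly over ν = 1…n−1, maximizing p
  within each bin, and reports p̂(e) as the midpoint of the winning bin.
* **Small-world structure:** same per-bin profiling over ν, with a bounded
  2-D (p, p_w) optimization inside each bin because (1−p_w)^{n−|Γ|} keeps
  p_w continuous there.
* A constant count series raises a "needs variance" error — the likelihood
  carries no information about p, mirroring the empirical exclusion rule.

**Standard errors** come from a central-finite-difference Hessian of the
negative log-likelihood at the optimum (relative steps max(1e−4, 1e−4·|θ|)),
SE = sqrt of the inverse-Hessian diagonal. A "paper" mode additionally
scales the inverse by 1/T; the wording that motivates it is ambiguous
between the Hessian of the total and of the average log-likelihood, so both
modes exist and the unscaled observed-information SE is the default (it is
the one whose calibration against the replicate SD is tested). For the
random structure the p_e direction is locally flat, so its SE is reported
as unavailable and the p SE falls back to the scalar curvature.

**Model selection** uses BIC = k·ln(T−1) − 2·loglik (k = 1 for the grid,
2 otherwise); the sample size is the number of transitions because the
likelihood is a product of T−1 terms.

## Bifurcation analysis and classification

Equilibria are found by iterating a map 1000 times from starting densities
{0.01, 0.99}, averaging the last 50 values per start, and merging limits
closer than 0.02; a tail that has not settled raises rather than being
silently merged. The critical point is located by a 0.001-step scan of the
equilibrium count followed by bisection to 1e−4. Near the pitchfork the
convergence rate degenerates, so the critical-point routine uses 5000
iterations instead of 1000; with the default budget the boundary estimate
would be biased upward by roughly 1e−3, which the larger budget reduces to
~1e−4 (the closed-form grid value ½(1 − 2^{|Γ|−1}/(|Γ|·C(|Γ|−1,⌊|Γ|/2⌋)))
is the test oracle). Classification consults the equilibrium set at p̂
directly — bistable iff two equilibria — rather than comparing p̂ to a
precomputed critical point, so it remains correct for maps whose bistable
region is not a simple interval; an estimate exactly at the critical point
is classified stable.

## Bimodality coefficient

BC = (s²+1)/(k+C) with moment skewness s, *excess* kurtosis k, and
C = 3(m−1)²/((m−2)(m−3)) where m is the number of time points. Excess
kurtosis makes the coefficient match the standard convention (normal ≈ 1/3,
balanced two-point mass → 1). The correction's "number of variables" is
interpreted as the number of observations, since the coefficient is
computed on a distribution over time. Population (biased) moment estimators
are the default; the bias-corrected variant is switchable. The bimodality
flag is strict (BC > 0.55).

## Preprocessing

Tri-state items (0 positive, 1 neither, 2 negative) collapse "neither" into
the positive state by default ({0,1} → 0, {2} → 1); the alternative collapse
is available. Continuous 0–100 items are recoded x → 100−x when reversed
(positively worded) and median-split per item per participant; ties at the
median go to 0 (the rule is "strictly above → 1" and ties are otherwise
unassigned). An exact 1-D 2-means dichotomizer is exposed behind the same
interface but is not the default. LOCF imputation carries the last observed
value forward per item; leading unobserved occasions are dropped (no
predecessor), and a drop-missing-occasions mode exists. Exclusion rules:
fewer than 5 completed occasions, or the rarer binary category below 5% of
responses pooled over the participant's item × occasion cells (a per-item
variant of the variance filter is available; the pooled reading was chosen
because the rule is stated for the participant's responses as a whole).
The packaged AMS metadata marks the 15 items whose response scale was
presented reversed; the HND metadata flags the ten positively worded mood
items as reverse-coded — the published description does not enumerate them,
so this default is this package's reading and is overridable in the
pipeline configuration.

## Synthetic data

The fixture generator simulates the SCA itself (graph per condition, known
p and structure, iid Bernoulli(0.5) initial states — an explicit stand-in
for sampling "a random number of active nodes"), so ground truth is known
by construction. This emulates the *structure* of empirical ESM panels
(T × n binary matrices, realistic T of tens to a few thousand) but none of
their measurement realities: no time-varying p, no node-specific
activation, no day/night beep structure, no informative missingness.
Passing cohort checks therefore demonstrates that the estimator and
classifier recover the truth when the model is correct (or when data come
from the automaton the model approximates) — not that the model is correct
for clinical data. The empirical cohort percentages reported alongside the
original analyses depend on restricted raw data and are out of scope here;
the pipeline's cohort checks instead require ≥ 80% correct verdicts on
automaton-generated cohorts in clearly bistable (p = 0.1) and clearly
stable (p = 0.45) regimes.

## Problem sizes used in the checked results

The acceptance computations use the study conditions as stated: equilibrium
targets iterate the map 1000 times; the grid error condition is n = 100,
T = 5000, p = 0.4 with 100 replications; the random-graph error condition
is n = 25, T = 50, p = 0.2, p_e = 0.1 with 100 replications (a fresh graph
per replication, degenerate constant series skipped as the exclusion rule
prescribes). Property tests use smaller T and replication counts chosen for
a fast default test run while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The small-world map's literal two-part form (no grid limit at p_w → 0)
  makes cross-structure BIC comparisons asymmetric for sparse wiring.
* The ν-profiled graph-parameter estimate is interval-identified at best
  (any p_e in the winning bin is an ML solution); its reported midpoint and
  missing SE reflect that honestly, and the estimate is known to be poor
  for sparse graphs where isolated nodes decouple from the density.
* Estimation error is largest for p near the critical point (flat
  likelihood at density ≈ 0.5), consistent with the simulation studies.
* A single static p per individual; time-varying or node-specific noise,
  continuous states, and scale-free graphs are out of scope.
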