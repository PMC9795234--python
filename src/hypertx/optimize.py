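"""Constrained global optimization by a stochastic-ranking evolution strategy.

The fitting machinery used throughout the package: a normalized
squared-distance objective between simulated and observed equilibrium
targets, a quadratic penalty for physiological box constraints sampled over
time, and a (μ, λ) evolution strategy whose selection ranks individuals by a
stochastic interleaving of objective and penalty comparisons (SRES).  The
stochastic ranking lets the search cross infeasible regions early while
converging to feasible optima.

References for the method class are the standard SRES literature; the
hyperparameter defaults (pf = 0.45, μ = 30, λ = 200) follow it and are all
overridable per problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FitTarget",
    "BoxConstraint",
    "OptimizationProblem",
    "OptimizationResult",
    "f_dist",
    "f_penalty",
    "stochastic_rank",
    "sres_minimize",
]


@dataclass(frozen=True)
class FitTarget:
    """One observed quantity to reproduce; its weight is its own value."""

    name: str
    observed: float
    extractor: str | None = None   # EquilibriumState field name, defaults to `name`

    def __post_init__(self) -> None:
        if self.observed <= 0:
            raise ValueError(
                f"target {self.name}: observed value must be positive "
                f"(weights are the observed values), got {self.observed}"
            )


@dataclass(frozen=True)
class BoxConstraint:
    """Physiological range Y_min <= Y(t) <= Y_max for a variable or parameter."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"constraint {self.name}: need lower < upper, "
                             f"got [{self.lower}, {self.upper}]")


@dataclass
class OptimizationProblem:
    names: Sequence[str]
    lower: np.ndarray
    upper: np.ndarray
    mu: int = 30
    lam: int = 200
    generations: int = 250
    pf: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound arrays must have equal shape")
        if not np.all(np.isfinite(self.lower)) or not np.all(np.isfinite(self.upper)):
            raise ValueError("search bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise ValueError("need lower < upper for every decision variable")
        if self.lam < self.mu:
            raise ValueError("lambda must be >= mu")
        if not 0.0 < self.pf < 1.0:
            raise ValueError("pf must lie in (0, 1)")


@dataclass
class OptimizationResult:
    x: np.ndarray
    objective: float
    penalty: float
    feasible: bool
    evaluations: int
    history: list[tuple[int, float, float]] = field(default_factory=list)


def f_dist(x: Sequence[float], x_exp: Sequence[float]) -> float:
    """Normalized sum of squared differences.

    ``Σ_i (ω_min/ω_i)·(X_i − X_i^exp)²`` with ``ω_i = X_i^exp`` and
    ``ω_min = min_i ω_i``; zero iff the simulated targets match exactly.
    """
    x = np.asarray(x, dtype=float)
    x_exp = np.asarray(x_exp, dtype=float)
    if x.shape != x_exp.shape or x.size < 1:
        raise ValueError("X and X_exp must be equally sized, nonempty vectors")
    if np.any(x_exp <= 0):
        raise ValueError("observed targets must be positive (they are the weights)")
    w = x_exp
    return float(np.sum((w.min() / w) * (x - x_exp) ** 2))


def f_penalty(series: Sequence[Sequence[float]],
              constraints: Sequence[BoxConstraint]) -> float:
    """Quadratic box-violation penalty summed over constraints and samples.

    ``Σ_t ( Σ_j max(0, Y_j^min − Y_j(t))² + Σ_j max(0, Y_j(t) − Y_j^max)² )``.
    ``series[j]`` holds the sampled values of constraint j; all constrained
    quantities must be sampled on the same time grid.
    """
    if len(series) != len(constraints):
        raise ValueError("one sampled series required per constraint")
    lengths = {len(s) for s in series}
    if len(lengths) > 1:
        raise ValueError("all constrained quantities must share one time grid")
    total = 0.0
    for s, c in zip(series, constraints):
        y = np.asarray(s, dtype=float)
        total += float(np.sum(np.maximum(0.0, c.lower - y) ** 2))
        total += float(np.sum(np.maximum(0.0, y - c.upper) ** 2))
    return total


def stochastic_rank(population: Sequence[tuple[float, float]], pf: float = 0.45,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Stochastic-ranking permutation (ascending, best first).

    Bubble-sort-like sweeps over adjacent pairs: when both individuals are
    feasible (zero penalty), or with probability ``pf`` otherwise, the pair is
    ordered by objective; otherwise by penalty.  Sweeping stops after a pass
    with no swaps.  Deterministic for a seeded generator; ties keep insertion
    order.
    """
    n = len(population)
    if n == 0:
        raise ValueError("cannot rank an empty population")
    if not 0.0 < pf < 1.0:
        raise ValueError("pf must lie in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    obj = np.array([p[0] for p in population], dtype=float)
    pen = np.array([p[1] for p in population], dtype=float)
    idx = np.arange(n)
    for _ in range(n):
        swapped = False
        u = rng.random(max(n - 1, 1))
        for j in range(n - 1):
            a, b = idx[j], idx[j + 1]
            both_feasible = pen[a] == 0.0 and pen[b] == 0.0
            by_objective = both_feasible or (u[j] < pf)
            if by_objective:
                worse = obj[a] > obj[b]
            else:
                worse = pen[a] > pen[b]
            if worse:
                idx[j], idx[j + 1] = b, a
                swapped = True
        if not swapped:
            break
    return idx


def sres_minimize(problem: OptimizationProblem,
                  evaluate: Callable[[np.ndarray], tuple[float, float]],
                  x0: np.ndarray | None = None) -> OptimizationResult:
    """(μ, λ) evolution strategy with stochastic-ranking selection.

    Log-normal self-adaptive per-coordinate step sizes, boundary reflection,
    and selection by :func:`stochastic_rank`.  Returns the best
    feasible-then-lowest-objective individual ever evaluated, with an
    infeasibility flag if no feasible point was found within the budget.
    ``x0``, when given, seeds one member of the initial population.
    Reproducible for a fixed ``problem.seed``.
    """
    rng = np.random.default_rng(problem.seed)
    lo, hi = problem.lower, problem.upper
    ndim = lo.size
    span = hi - lo
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(ndim))
    tau_prime = 1.0 / np.sqrt(2.0 * ndim)

    xs = lo + rng.random((problem.lam, ndim)) * span
    if x0 is not None:
        xs[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    sigmas = np.full((problem.lam, ndim), span / 6.0)

    best: OptimizationResult | None = None
    evals = 0
    history: list[tuple[int, float, float]] = []

    def better(o: float, p: float, res: OptimizationResult | None) -> bool:
        if res is None:
            return True
        if (p == 0.0) != res.feasible:
            return p == 0.0
        if p == 0.0:
            return o < res.objective
        return (p, o) < (res.penalty, res.objective)

    for gen in range(problem.generations):
        scored = []
        for i in range(xs.shape[0]):
            o, p = evaluate(xs[i])
            evals += 1
            if not np.isfinite(o):
                o = 1e30
            if not np.isfinite(p):
                p = 1e30
            scored.append((o, p))
            if better(o, p, best):
                best = OptimizationResult(xs[i].copy(), o, p, p == 0.0, 0)
        order = stochastic_rank(scored, problem.pf, rng)
        parents_x = xs[order[: problem.mu]]
        parents_s = sigmas[order[: problem.mu]]
        history.append((gen, scored[order[0]][0], scored[order[0]][1]))

        # recombine (discrete for x, intermediate for sigma) and mutate
        pick = rng.integers(0, problem.mu, size=problem.lam)
        mate = rng.integers(0, problem.mu, size=problem.lam)
        child_x = parents_x[pick].copy()
        child_s = 0.5 * (parents_s[pick] + parents_s[mate])
        g = rng.standard_normal((problem.lam, 1))
        child_s = child_s * np.exp(tau_prime * g + tau * rng.standard_normal((problem.lam, ndim)))
        np.clip(child_s, 1e-12 * span, span, out=child_s)
        child_x = child_x + child_s * rng.standard_normal((problem.lam, ndim))
        # boundary reflection
        for _ in range(4):
            over = child_x > hi
            child_x[over] = (2 * hi - child_x)[over]
            under = child_x < lo
            child_x[under] = (2 * lo - child_x)[under]
        np.clip(child_x, lo, hi, out=child_x)
        xs, sigmas = child_x, child_s

    assert best is not None
    best.evaluations = evals
    best.history = history
    return best
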