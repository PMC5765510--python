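"""Derivative-free minimisers used for progress-curve fitting.

Two algorithm families are provided, both operating on box-bounded
continuous problems (the fitting layer hands them log10-transformed rate
constants):

* a multi-start Nelder-Mead simplex (scipy's implementation, restarted from
  several seeded initial points and polished from the incumbent);
* a particle-swarm pattern-search hybrid: a standard inertia-weight particle
  swarm explores globally, then a compass (coordinate pattern) search
  polishes the incumbent to high precision.

Both are deterministic for a fixed seed. The objective may return ``inf``
for infeasible points (failed simulations); both methods tolerate that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize


@dataclass
class OptimizeOutcome:
    x: np.ndarray
    fun: float
    n_evaluations: int
    converged: bool
    trace: list


class _CountedFunction:
    def __init__(self, fun):
        self.fun = fun
        self.count = 0
        self.best_x = None
        self.best_f = np.inf

    def __call__(self, x):
        self.count += 1
        f = float(self.fun(x))
        if np.isnan(f):
            f = np.inf
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, dtype=float)
        return f


def _clip(x, lower, upper):
    return np.minimum(np.maximum(x, lower), upper)


def compass_search(
    fun,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    step: float = 0.25,
    step_tol: float = 1e-9,
    max_evaluations: int = 20000,
):
    """Coordinate pattern search: poll +-step along each axis, move on
    improvement, halve the step when a full poll fails."""
    x = _clip(np.asarray(x0, dtype=float), lower, upper)
    fx = fun(x)
    n = x.size
    evals = 1
    while step > step_tol and evals < max_evaluations:
        improved = False
        for i in range(n):
            for sign in (+1.0, -1.0):
                trial = x.copy()
                trial[i] = np.clip(trial[i] + sign * step, lower[i], upper[i])
                if trial[i] == x[i]:
                    continue
                ft = fun(trial)
                evals += 1
                if ft < fx:
                    x, fx = trial, ft
                    improved = True
                    break
        if not improved:
            step *= 0.5
    return x, fx


def nelder_mead_multistart(
    fun,
    lower: np.ndarray,
    upper: np.ndarray,
    seed: int = 0,
    n_starts: int = 5,
    x0: np.ndarray | None = None,
    xatol: float = 1e-7,
    fatol: float = 1e-14,
    maxiter: int | None = None,
) -> OptimizeOutcome:
    """Adjusted Nelder-Mead simplex with seeded multi-start.

    The first start is ``x0`` (or the box centre); the remaining starts are
    drawn uniformly inside the box from ``seed``. The best start's optimum
    is re-polished with a second simplex run before being returned.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    f = _CountedFunction(fun)
    rng = np.random.default_rng(seed)
    starts = []
    starts.append(
        np.asarray(x0, dtype=float) if x0 is not None else 0.5 * (lower + upper)
    )
    for _ in range(max(0, n_starts - 1)):
        starts.append(lower + rng.random(lower.size) * (upper - lower))

    bounds = list(zip(lower, upper))
    options = {"xatol": xatol, "fatol": fatol, "adaptive": True}
    if maxiter is not None:
        options["maxiter"] = maxiter
    trace = []
    best = None
    for s in starts:
        res = minimize(f, _clip(s, lower, upper), method="Nelder-Mead",
                       bounds=bounds, options=options)
        trace.append({"start": s.tolist(), "fun": float(res.fun)})
        if best is None or res.fun < best.fun:
            best = res
    # polish the incumbent
    res = minimize(f, best.x, method="Nelder-Mead", bounds=bounds,
                   options=options)
    if res.fun > best.fun:
        res = best
    x = f.best_x if f.best_f < res.fun else np.asarray(res.x, dtype=float)
    fx = min(f.best_f, float(res.fun))
    return OptimizeOutcome(
        x=_clip(x, lower, upper),
        fun=fx,
        n_evaluations=f.count,
        converged=bool(np.isfinite(fx)),
        trace=trace,
    )


def particle_swarm_pattern_search(
    fun,
    lower: np.ndarray,
    upper: np.ndarray,
    seed: int = 0,
    n_particles: int = 20,
    iterations: int = 60,
    inertia: float = 0.72,
    cognitive: float = 1.49,
    social: float = 1.49,
    polish_step: float = 0.25,
    polish_tol: float = 1e-9,
) -> OptimizeOutcome:
    """Particle swarm global search followed by a compass-search polish of
    the swarm incumbent. Deterministic for a fixed seed."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n = lower.size
    f = _CountedFunction(fun)
    rng = np.random.default_rng(seed)

    span = upper - lower
    x = lower + rng.random((n_particles, n)) * span
    v = (rng.random((n_particles, n)) - 0.5) * span * 0.2
    pbest_x = x.copy()
    pbest_f = np.array([f(xi) for xi in x])
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    trace = [{"iteration": 0, "best": gbest_f}]

    for it in range(1, iterations + 1):
        r1 = rng.random((n_particles, n))
        r2 = rng.random((n_particles, n))
        v = (
            inertia * v
            + cognitive * r1 * (pbest_x - x)
            + social * r2 * (gbest_x[None, :] - x)
        )
        x = _clip(x + v, lower, upper)
        for i in range(n_particles):
            fi = f(x[i])
            if fi < pbest_f[i]:
                pbest_f[i] = fi
                pbest_x[i] = x[i]
                if fi < gbest_f:
                    gbest_f = float(fi)
                    gbest_x = x[i].copy()
        trace.append({"iteration": it, "best": gbest_f})

    gbest_x, gbest_f = compass_search(
        f, gbest_x, lower, upper, step=polish_step, step_tol=polish_tol
    )
    return OptimizeOutcome(
        x=gbest_x,
        fun=float(gbest_f),
        n_evaluations=f.count,
        converged=bool(np.isfinite(gbest_f)),
        trace=trace,
    )
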