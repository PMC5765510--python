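"""Progress-curve parameter estimation.

The estimator follows the statsmodels idiom: :class:`ProgressCurveModel` is
built from one or more :class:`~gdpman.datasets.TimeSeriesDataset` objects
plus the names of the rate constants to estimate; its :meth:`fit` runs a
derivative-free search (multi-start Nelder-Mead simplex or a particle-swarm
pattern-search hybrid) in log10 parameter space and returns a
:class:`ProgressCurveResults` carrying the estimates, the objective, the
residuals and a ``summary()`` table.

The objective is a weighted sum of squared residuals over datasets, observed
species, sampling times and replicates, with each species scaled by its
per-dataset maximum absolute value so that µM-scale nucleotides and mM-scale
sugars contribute comparably. The constants span more than twelve decades
(k7 ~ 1e10), hence the log-space search with default bounds [1e-6, 1e12].

Following the study's protocol, each experiment collection is fitted
independently by default ("one fit per data set"); joint fits are simply a
model built over several collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._optimize import nelder_mead_multistart, particle_swarm_pattern_search
from .datasets import TimeSeriesDataset
from .exceptions import (
    ConfigurationError,
    FitFailureError,
    GdpmanError,
    ValidationError,
)
from .model import CascadeModel, RateParameters
from .simulate import simulate

__all__ = [
    "DEFAULT_BOUNDS",
    "ProgressCurveModel",
    "ProgressCurveResults",
    "objective",
    "fit",
    "refit_cascade",
]

#: default native-unit search box; the constants span >12 decades
DEFAULT_BOUNDS = (1e-6, 1e12)

ALGORITHMS = ("nelder_mead", "particle_swarm_pattern_search")


class ProgressCurveModel:
    """Least-squares estimation problem for cascade rate constants.

    Parameters
    ----------
    datasets : sequence of TimeSeriesDataset
        Progress curves to fit; every dataset is simulated under its own
        design but with the shared candidate parameters.
    variant : str, optional
        Model variant used for simulation; defaults to the (common) variant
        of the datasets.
    free : sequence of str
        Names of the rate constants to estimate.
    bounds : mapping name -> (lower, upper), optional
        Positive native-unit box constraints; default [1e-6, 1e12].
    fixed : mapping name -> value, optional
        Constants frozen at non-default values.
    base_parameters : RateParameters, optional
        Values of all constants not being estimated.
    weighting : mapping species -> scale, optional
        Overrides the per-dataset max-|value| residual scaling.
    """

    def __init__(
        self,
        datasets: Sequence[TimeSeriesDataset],
        free: Sequence[str],
        variant: str | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        fixed: Mapping[str, float] | None = None,
        base_parameters: RateParameters | None = None,
        ppa_mode: str = "fast_kinetic",
        weighting: Mapping[str, float] | None = None,
        rtol: float = 1e-7,
        atol: float = 1e-11,
    ):
        self.datasets = list(datasets)
        self.free = tuple(free)
        if not self.free:
            raise ValidationError("at least one free parameter is required")
        self.fixed = dict(fixed or {})
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValidationError(
                f"parameters cannot be both free and fixed: {sorted(overlap)}"
            )
        base = base_parameters if base_parameters is not None else RateParameters()
        self.base_parameters = base.replace(**self.fixed)
        valid_names = set(self.base_parameters.as_dict())
        unknown = set(self.free) - valid_names
        if unknown:
            raise ConfigurationError(f"unknown free parameters: {sorted(unknown)}")
        if variant is None:
            variants = {ds.variant for ds in self.datasets}
            if len(variants) != 1:
                raise ValidationError(
                    "datasets span several variants; pass variant= explicitly"
                )
            variant = variants.pop()
        self.variant = variant
        self.ppa_mode = ppa_mode
        self.rtol = rtol
        self.atol = atol

        self.bounds: dict[str, tuple[float, float]] = {}
        bounds = dict(bounds or {})
        for name in self.free:
            lo, hi = bounds.get(name, DEFAULT_BOUNDS)
            if not (0 < lo < hi):
                raise ValidationError(
                    f"bounds for {name!r} must satisfy 0 < lower < upper"
                )
            self.bounds[name] = (float(lo), float(hi))

        # validate dataset species against the model state space and
        # precompute residual scales
        probe = CascadeModel(self.variant, self.base_parameters, ppa_mode)
        self._scales = []
        for ds in self.datasets:
            for sp in ds.species:
                probe.species_index(sp)
            scale = np.empty(len(ds.species))
            for j, sp in enumerate(ds.species):
                if weighting and sp in weighting:
                    scale[j] = weighting[sp]
                else:
                    scale[j] = np.max(np.abs(ds.values[:, j, :]))
                if scale[j] <= 0:
                    scale[j] = 1.0  # species never detected: unweighted
            self._scales.append(scale)

    # -- objective -------------------------------------------------------

    def parameters_from(self, values: Sequence[float] | Mapping[str, float]) -> RateParameters:
        if isinstance(values, Mapping):
            values = [values[name] for name in self.free]
        return self.base_parameters.replace(**dict(zip(self.free, values)))

    def residuals(self, values) -> list[np.ndarray]:
        """Per-dataset scaled residual arrays (times x species x replicates).

        Raises on simulation failure; :meth:`objective` maps failures to the
        ``inf`` sentinel instead.
        """
        params = self.parameters_from(values)
        model = CascadeModel(self.variant, params, self.ppa_mode)
        out = []
        for ds, scale in zip(self.datasets, self._scales):
            res = simulate(model, ds.design, rtol=self.rtol, atol=self.atol,
                           t_eval=ds.times)
            pred = res.sampled(ds.species, ds.times)
            resid = (pred[:, :, None] - ds.values) / scale[None, :, None]
            out.append(resid)
        return out

    def objective(self, values) -> float:
        """Weighted sum of squared residuals; ``inf`` if any simulation
        fails at the candidate parameters."""
        try:
            residuals = self.residuals(values)
        except GdpmanError:
            return float("inf")
        return float(sum(np.sum(r * r) for r in residuals))

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        method: str = "nelder_mead",
        seed: int = 0,
        n_starts: int = 5,
        start: Mapping[str, float] | Sequence[float] | None = None,
        **options,
    ) -> "ProgressCurveResults":
        """Estimate the free constants.

        ``method`` is ``"nelder_mead"`` (multi-start simplex) or
        ``"particle_swarm_pattern_search"``. The search runs in log10
        space inside the bounds box; results are deterministic for a fixed
        (method, seed, problem). ``start`` optionally seeds the first
        simplex at a native-unit point.
        """
        if method not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {method!r}; expected one of {ALGORITHMS}"
            )
        lower = np.log10([self.bounds[n][0] for n in self.free])
        upper = np.log10([self.bounds[n][1] for n in self.free])

        def log_objective(z):
            return self.objective(10.0 ** np.asarray(z))

        x0 = None
        if start is not None:
            if isinstance(start, Mapping):
                start = [start[n] for n in self.free]
            x0 = np.log10(np.asarray(start, dtype=float))

        if method == "nelder_mead":
            outcome = nelder_mead_multistart(
                log_objective, lower, upper, seed=seed, n_starts=n_starts,
                x0=x0, **options,
            )
        else:
            outcome = particle_swarm_pattern_search(
                log_objective, lower, upper, seed=seed, **options,
            )
        if not np.isfinite(outcome.fun):
            raise FitFailureError(
                "no evaluated parameter vector produced a successful simulation"
            )
        estimates = dict(zip(self.free, 10.0 ** outcome.x))
        return ProgressCurveResults(
            model=self,
            method=method,
            seed=seed,
            estimates=estimates,
            objective=float(outcome.fun),
            n_evaluations=outcome.n_evaluations,
            converged=outcome.converged,
            trace=outcome.trace,
        )


@dataclass
class ProgressCurveResults:
    """Fit results: point estimates, objective value and provenance."""

    model: ProgressCurveModel
    method: str
    seed: int
    estimates: dict[str, float]
    objective: float
    n_evaluations: int
    converged: bool
    trace: list = field(default_factory=list)

    @property
    def parameters(self) -> RateParameters:
        """Full constant set with the estimates substituted."""
        return self.model.parameters_from(self.estimates)

    def residuals(self) -> list[np.ndarray]:
        return self.model.residuals([self.estimates[n] for n in self.model.free])

    def summary(self) -> str:
        lines = [
            "Progress-curve fit",
            "==================",
            f"variant:        {self.model.variant}",
            f"datasets:       {len(self.model.datasets)}",
            f"algorithm:      {self.method} (seed {self.seed})",
            f"objective:      {self.objective:.6g}",
            f"evaluations:    {self.n_evaluations}",
            f"converged:      {self.converged}",
            "",
            f"{'parameter':<10} {'estimate':>14} {'lower':>10} {'upper':>10}",
        ]
        for name in self.model.free:
            lo, hi = self.model.bounds[name]
            lines.append(
                f"{name:<10} {self.estimates[name]:>14.6g} {lo:>10.3g} {hi:>10.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": self.model.variant,
            "free": list(self.model.free),
            "bounds": {k: list(v) for k, v in self.model.bounds.items()},
            "estimates": self.estimates,
            "objective": self.objective,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "method": self.method,
            "seed": self.seed,
            "n_datasets": len(self.model.datasets),
        }


# -- functional surface --------------------------------------------------


def objective(problem: ProgressCurveModel, values) -> float:
    return problem.objective(values)


def fit(problem: ProgressCurveModel, algorithm: str = "nelder_mead",
        seed: int = 0, **options) -> ProgressCurveResults:
    return problem.fit(method=algorithm, seed=seed, **options)


def refit_cascade(
    datasets: Sequence[TimeSeriesDataset],
    parameter_names: Sequence[str] = ("k4",),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    base_parameters: RateParameters | None = None,
    method: str = "nelder_mead",
    seed: int = 0,
    **options,
) -> ProgressCurveResults:
    """Refit selected constants against multi-enzyme cascade data while all
    other constants stay frozen at their single-enzyme values.

    The two protocol variants are ``("k4",)`` on plain-cascade data (probing
    enhanced ManB/ManC activity in the enzyme mixture) and ``("k2", "k3")``
    on Alg1-coupled data (probing inhibited nucleotide-kinase activity).
    """
    names = tuple(parameter_names)
    if names not in (("k4",), ("k2", "k3")):
        raise ConfigurationError(
            "cascade refits adjust either ('k4',) or ('k2', 'k3')"
        )
    variants = {ds.variant for ds in datasets}
    if not variants <= {"cascade", "cascade_alg1"}:
        raise ValidationError(
            f"cascade refits need cascade datasets, got variants {sorted(variants)}"
        )
    problem = ProgressCurveModel(
        datasets,
        free=names,
        variant=max(variants),  # cascade_alg1 if any dataset is coupled
        bounds=bounds,
        base_parameters=base_parameters,
    )
    return problem.fit(method=method, seed=seed, **options)
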