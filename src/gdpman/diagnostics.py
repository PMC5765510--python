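"""Experimental-design QC: Selwyn's enzyme-inactivation test and
conservation checking.

Selwyn's test replots progress curves measured at several enzyme loadings
against e0*t (loading times time). If product formation depends on enzyme
concentration only through the product e0*t — true for any rate law linear
in a stable enzyme's concentration — the curves coincide; systematic spread
indicates enzyme inactivation (or another loading-dependent artefact)
during the assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .model import CascadeModel, RateParameters
from .simulate import ExperimentDesign, SimulationResult, simulate

__all__ = [
    "SelwynCurve",
    "SelwynReport",
    "selwyn_statistic",
    "selwyn_test",
    "ConservationReport",
    "check_conservation",
]


@dataclass(frozen=True)
class SelwynCurve:
    """One progress curve at enzyme loading ``e0`` (g/L): product
    concentration (mol/L) against time (min)."""

    e0: float
    times: np.ndarray
    product: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "product", np.asarray(self.product, dtype=float))
        if self.e0 <= 0:
            raise ValidationError("enzyme loading must be positive")
        if self.times.shape != self.product.shape or self.times.size < 2:
            raise ValidationError("curve needs matching times/product arrays")


@dataclass
class SelwynReport:
    """Selwyn-test outcome: the e0*t-reparameterised curves, the normalised
    overlap statistic (mean over a common e0*t grid of the spread across
    curves divided by the pooled mean) and the verdict."""

    curves: list[SelwynCurve]
    grid: np.ndarray
    interpolated: np.ndarray
    overlap_statistic: float
    threshold: float

    @property
    def verdict(self) -> str:
        return (
            "no_inactivation"
            if self.overlap_statistic < self.threshold
            else "inactivation_suspected"
        )


def selwyn_statistic(
    curves: Sequence[SelwynCurve | tuple],
    threshold: float = 0.05,
    n_grid: int = 100,
) -> SelwynReport:
    """Compute the Selwyn overlap statistic for >= 2 loadings.

    Each curve is reparameterised on the e0*t axis and linearly interpolated
    onto a common grid spanning the intersection of the supports; the
    statistic averages (max - min across curves) / (mean across curves) over
    grid points with non-negligible pooled mean. Zero for exactly coincident
    curves; the default verdict threshold is 0.05.
    """
    curves = [c if isinstance(c, SelwynCurve) else SelwynCurve(*c) for c in curves]
    if len(curves) < 2:
        raise ValidationError("Selwyn's test needs curves at >= 2 loadings")
    taus = [c.e0 * c.times for c in curves]
    lo = max(t.min() for t in taus)
    hi = min(t.max() for t in taus)
    if hi <= lo:
        raise ValidationError(
            "progress curves have non-overlapping e0*t supports"
        )
    grid = np.linspace(lo, hi, n_grid)
    interp = np.vstack([np.interp(grid, tau, c.product)
                        for tau, c in zip(taus, curves)])
    spread = interp.max(axis=0) - interp.min(axis=0)
    pooled = interp.mean(axis=0)
    scale = float(np.max(np.abs(pooled)))
    mask = pooled > max(scale, 1e-30) * 1e-9
    stat = float(np.mean(spread[mask] / pooled[mask])) if mask.any() else 0.0
    return SelwynReport(
        curves=curves,
        grid=grid,
        interpolated=interp,
        overlap_statistic=stat,
        threshold=threshold,
    )


def selwyn_test(
    variant: str,
    base_design: ExperimentDesign,
    enzyme: str,
    loadings: Sequence[float],
    product: str,
    parameters: RateParameters | None = None,
    enzyme_half_life: float | None = None,
    threshold: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SelwynReport:
    """Simulate ``base_design`` at several loadings of ``enzyme`` and run
    Selwyn's test on the ``product`` curves.

    ``enzyme_half_life`` (min) injects first-order enzyme inactivation —
    the positive-control oracle for a decaying enzyme.
    """
    if len(loadings) < 2:
        raise ValidationError("need >= 2 enzyme loadings")
    model = CascadeModel(variant, parameters)
    # evaluate every loading on time points mapping onto one shared e0*t
    # grid, so the overlap statistic measures kinetics rather than
    # interpolation error
    tau_grid = np.linspace(0.0, min(loadings) * base_design.t_end, 256)
    curves = []
    for e0 in loadings:
        loadings_map = dict(base_design.enzyme_loadings)
        loadings_map[enzyme] = float(e0)
        design = base_design.replace(
            enzyme_loadings=loadings_map,
            enzyme_half_lives=(
                {enzyme: enzyme_half_life} if enzyme_half_life else None
            ),
        )
        result = simulate(model, design, rtol=rtol, atol=atol,
                          t_eval=tau_grid / e0)
        curves.append(SelwynCurve(float(e0), result.times, result[product]))
    return selwyn_statistic(curves, threshold=threshold)


@dataclass
class ConservationReport:
    """Worst relative drift of each moiety pool over a trajectory."""

    drift: Mapping[str, float]
    worst_pool: str
    worst_time: float
    tolerance: float

    @property
    def ok(self) -> bool:
        return self.drift[self.worst_pool] <= self.tolerance

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "OK" if self.ok else "VIOLATED"
        return (
            f"conservation {status}: worst pool {self.worst_pool!r} drift "
            f"{self.drift[self.worst_pool]:.3g} (tol {self.tolerance:g}) "
            f"at t = {self.worst_time:.4g} min"
        )


def check_conservation(
    result: SimulationResult, tolerance: float = 1e-9
) -> ConservationReport:
    """Verify that every moiety pool stays constant along a simulated
    trajectory to relative ``tolerance``; the report names the worst pool
    and the time of its worst excursion."""
    model = result.model
    conc = np.maximum(result.concentrations, 0.0)
    worst_pool, worst_time, worst_drift = "", 0.0, -1.0
    drift: dict[str, float] = {}
    for pool in model.conservation_pools(conc[:, 0]):
        from .model import MOIETY_POOLS

        content = MOIETY_POOLS[pool]
        trace = np.zeros(conc.shape[1])
        for sp, coeff in content.items():
            trace += coeff * conc[model.species_index(sp)]
        scale = max(abs(trace[0]), 1e-30)
        rel = np.abs(trace - trace[0]) / scale
        k = int(np.argmax(rel))
        drift[pool] = float(rel[k])
        if rel[k] > worst_drift:
            worst_drift = float(rel[k])
            worst_pool = pool
            worst_time = float(result.times[k])
    return ConservationReport(
        drift=drift,
        worst_pool=worst_pool,
        worst_time=worst_time,
        tolerance=tolerance,
    )
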