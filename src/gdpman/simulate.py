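"""ODE integration of the cascade and the derived progress-curve observables.

The system is integrated with a stiff-capable solver (LSODA by default; the
pyrophosphatase step makes the full cascade moderately stiff). Observables
mirror what is typically reported for one-pot cascade reactions: product
titre at a time point, yield against a limiting reference species, the
steady (post-lag) production rate from an ordinary least-squares window fit,
lag time, equilibrium mass-action ratios and time-to-conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    ConsistencyError,
    ConvergenceError,
    SolverError,
    ValidationError,
)
from .model import ENZYMES, METABOLITES, POLYP, SPECIES_ORDER, CascadeModel

__all__ = [
    "DEFAULT_SAMPLE_TIMES",
    "ExperimentDesign",
    "SimulationResult",
    "simulate",
    "yield_vs_reference",
    "steady_rate",
    "equilibrium_ratio",
    "time_to_fraction",
    "standard_cascade_design",
    "coupled_cascade_design",
]

logger = logging.getLogger(__name__)

#: default sampling schedule (minutes), matching a dense progress-curve assay
DEFAULT_SAMPLE_TIMES = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0)

_DEFAULT_METADATA = {"pH": 7.5, "temperature_C": 30.0, "MgCl2_mM": 10.0}

#: polyphosphate operating point the rate constants are valid at:
#: 4 mM chains of average length 14 phosphate units
POLYP_STANDARD_MM = 4.0
POLYP_CHAIN_LENGTH = 14


@dataclass(frozen=True)
class ExperimentDesign:
    """One reaction setup: initial concentrations (mol/L), enzyme loadings
    (g/L), duration and sampling schedule (min), assay metadata and the
    replicate count.

    ``enzyme_half_lives`` (min) injects first-order enzyme inactivation;
    it is only used by diagnostics oracles, real designs leave it unset.
    ``observed_species`` restricts which species the detector reports
    (None = every metabolite except the PolyP bookkeeping pool).
    """

    initial_concentrations: Mapping[str, float]
    enzyme_loadings: Mapping[str, float]
    t_end: float = 240.0
    sample_times: Sequence[float] | None = None
    metadata: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_METADATA))
    replicates: int = 1
    enzyme_half_lives: Mapping[str, float] | None = None
    observed_species: tuple[str, ...] | None = None
    name: str = ""

    def __post_init__(self):
        if self.sample_times is None:
            # default schedule truncated to the experiment duration
            times = [t for t in DEFAULT_SAMPLE_TIMES if t < self.t_end]
            times.append(float(self.t_end))
            object.__setattr__(self, "sample_times", tuple(times))
        times = np.asarray(self.sample_times, dtype=float)
        if times.size < 1 or np.any(np.diff(times) <= 0):
            raise ValidationError("sample_times must be strictly increasing")
        if times[0] < 0 or times[-1] > self.t_end:
            raise ValidationError("sample_times must lie within [0, t_end]")
        for name, value in self.initial_concentrations.items():
            if name not in SPECIES_ORDER:
                raise ValidationError(f"unknown species {name!r} in design")
            if value < 0:
                raise ValidationError(f"negative initial concentration for {name!r}")
        for name, value in self.enzyme_loadings.items():
            if name not in ENZYMES:
                raise ValidationError(f"unknown enzyme {name!r} in design")
            if value < 0:
                raise ValidationError(f"negative loading for enzyme {name!r}")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        object.__setattr__(self, "sample_times", tuple(float(t) for t in times))
        if self.observed_species is not None:
            object.__setattr__(self, "observed_species", tuple(self.observed_species))

    def initial_state(self, model: CascadeModel) -> np.ndarray:
        y0 = np.zeros(model.n_species)
        for name, value in self.initial_concentrations.items():
            y0[model.species_index(name)] = float(value)
        for name, value in self.enzyme_loadings.items():
            y0[model.species_index(name)] = float(value)
        return y0

    def observed(self) -> tuple[str, ...]:
        if self.observed_species is not None:
            return self.observed_species
        return METABOLITES

    def replace(self, **updates) -> "ExperimentDesign":
        import dataclasses

        return dataclasses.replace(self, **updates)


def standard_cascade_design(replicates: int = 4, **overrides) -> ExperimentDesign:
    """The reference multi-enzyme run: mannose 6 mM, ADP and GDP 0.8 mM each,
    PolyP14 4 mM (56 mM phosphate-equivalents); loadings glk 0.5, ppk2 0.05,
    manbc 0.3, ppa 0.1 g/L; 240 min at pH 7.5, 30 degC, 10 mM MgCl2."""
    base = dict(
        initial_concentrations={
            "man": 6e-3,
            "ADP": 0.8e-3,
            "GDP": 0.8e-3,
            POLYP: POLYP_STANDARD_MM * 1e-3 * POLYP_CHAIN_LENGTH,
        },
        enzyme_loadings={"glk": 0.5, "ppk2": 0.05, "manbc": 0.3, "ppa": 0.1},
        t_end=240.0,
        sample_times=DEFAULT_SAMPLE_TIMES,
        replicates=replicates,
        observed_species=("ADP", "ATP", "GDP", "GTP", "GDPM"),
        name="cascade_standard",
    )
    base.update(overrides)
    return ExperimentDesign(**base)


def coupled_cascade_design(replicates: int = 3, **overrides) -> ExperimentDesign:
    """The Alg1-coupled run: the standard cascade plus 0.1 g/L Alg1(dTM) and
    0.7 mM phytanyl-PP-(GlcNAc)2 acceptor."""
    design = standard_cascade_design(replicates=replicates)
    conc = dict(design.initial_concentrations)
    conc["Phyt"] = 0.7e-3
    loadings = dict(design.enzyme_loadings)
    loadings["alg1"] = 0.1
    base = dict(
        initial_concentrations=conc,
        enzyme_loadings=loadings,
        t_end=design.t_end,
        sample_times=design.sample_times,
        replicates=replicates,
        observed_species=("ADP", "ATP", "GDP", "GTP", "GDPM", "Man1"),
        name="cascade_alg1_standard",
    )
    base.update(overrides)
    return ExperimentDesign(**base)


@dataclass
class SimulationResult:
    """Dense simulated trajectories plus per-reaction rate traces.

    ``concentrations`` is species x time (canonical species order of the
    model), ``reaction_rates`` is reaction x time. ``solver_report`` records
    tolerances, step statistics, clip events and conservation drift.
    """

    model: CascadeModel
    design: ExperimentDesign
    times: np.ndarray
    concentrations: np.ndarray
    reaction_rates: np.ndarray
    solver_report: dict

    @property
    def species(self) -> tuple[str, ...]:
        return self.model.species_names

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return self.model.reaction_ids

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[self.model.species_index(species)]

    def at(self, species: str, time: float) -> float:
        """Concentration of ``species`` at ``time`` (linear interpolation)."""
        return float(np.interp(time, self.times, self[species]))

    def final(self, species: str) -> float:
        return float(self[species][-1])

    def sampled(self, species: Sequence[str], times: Sequence[float]) -> np.ndarray:
        """Matrix len(times) x len(species) interpolated onto ``times``."""
        out = np.empty((len(times), len(species)))
        for j, sp in enumerate(species):
            out[:, j] = np.interp(times, self.times, self[sp])
        return out

    def to_frame(self):
        """Tidy DataFrame (time_min, species, concentration_M) of the
        metabolite trajectories."""
        import pandas as pd

        rows = []
        for sp in METABOLITES + (POLYP,):
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "species": sp,
                        "concentration_M": self[sp],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def plot(self, species: Sequence[str] | None = None, ax=None):
        """Plot selected trajectories (µM vs minutes). Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sp in species or ("GDPM", "GDP", "GTP", "ADP", "ATP"):
            ax.plot(self.times, 1e6 * self[sp], label=sp)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (µM)")
        ax.legend()
        return ax


def _dense_grid(design: ExperimentDesign, n: int = 481) -> np.ndarray:
    grid = np.linspace(0.0, design.t_end, n)
    return np.unique(np.concatenate([grid, np.asarray(design.sample_times)]))


def simulate(
    model: CascadeModel,
    design: ExperimentDesign,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    t_eval: Sequence[float] | None = None,
    method: str = "LSODA",
    conservation_tol: float = 1e-7,
) -> SimulationResult:
    """Integrate ``model`` under ``design`` and return trajectories.

    ``t_eval`` defaults to a dense grid over [0, t_end] merged with the
    design's sampling schedule. In ``strict_instant`` pyrophosphatase mode
    any initial PP is converted to 2 Pi before integration (the algebraic
    elimination of the instantaneously-hydrolysed pool).

    Raises :class:`SolverError` on integration failure (carrying the last
    valid time) and :class:`ConsistencyError` if a moiety pool drifts beyond
    ``conservation_tol`` (relative).
    """
    y0 = design.initial_state(model)
    if model.ppa_mode == "strict_instant" and model._has.get("r6"):
        i_pp = model.species_index("PP")
        i_pi = model.species_index("Pi")
        y0[i_pi] += 2.0 * y0[i_pp]
        y0[i_pp] = 0.0

    times = (
        _dense_grid(design)
        if t_eval is None
        else np.asarray(t_eval, dtype=float)
    )
    decay = None
    if design.enzyme_half_lives:
        decay = {
            enz: np.log(2.0) / float(hl)
            for enz, hl in design.enzyme_half_lives.items()
        }
    rhs, info = model.make_rhs(decay)

    sol = solve_ivp(
        rhs,
        (0.0, float(design.t_end)),
        y0,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SolverError(
            f"integration failed at t = {last:.4g} min: {sol.message}",
            last_valid_time=last,
        )

    conc = sol.y
    clipped = np.maximum(conc, 0.0)
    rates = np.empty((len(model.reactions), conc.shape[1]))
    for k in range(conc.shape[1]):
        rates[:, k] = model._rates_raw(clipped[:, k])

    pools0 = model.conservation_pools(np.maximum(y0, 0.0))
    drift = {}
    for pool, total0 in pools0.items():
        trace = _pool_trace(model, clipped, pool)
        scale = max(abs(total0), 1e-30)
        drift[pool] = float(np.max(np.abs(trace - total0)) / scale)
    worst_pool = max(drift, key=drift.get)
    if drift[worst_pool] > conservation_tol:
        raise ConsistencyError(
            f"moiety pool {worst_pool!r} drifted by relative "
            f"{drift[worst_pool]:.3g} (> {conservation_tol:g})"
        )

    polyp = conc[model.species_index(POLYP)]
    polyp_ok = bool(np.min(polyp) >= -atol)
    if not polyp_ok:
        logger.warning(
            "PolyP bookkeeping pool went negative (min %.3g mol/L); the rate "
            "constants are only valid at the 4 mM PolyP operating point",
            float(np.min(polyp)),
        )

    report = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "nfev": int(sol.nfev),
        "njev": int(getattr(sol, "njev", 0) or 0),
        "clip_events": info["clip_events"],
        "min_concentration": float(conc[: len(METABOLITES) + 1].min()),
        "clipped_at_zero": bool(conc[: len(METABOLITES) + 1].min() < 0),
        "conservation_drift": drift,
        "polyp_pool_nonnegative": polyp_ok,
        "polyp_within_calibrated_regime": polyp_ok,
        "message": str(sol.message),
    }
    return SimulationResult(model, design, sol.t, conc, rates, report)


def _pool_trace(model: CascadeModel, conc: np.ndarray, pool: str) -> np.ndarray:
    from .model import MOIETY_POOLS

    content = MOIETY_POOLS[pool]
    out = np.zeros(conc.shape[1])
    for sp, coeff in content.items():
        out += coeff * conc[model.species_index(sp)]
    return out


# -- observables ---------------------------------------------------------


def yield_vs_reference(
    result: SimulationResult, product: str, reference_amount: float
) -> float:
    """Final-time yield of ``product`` as a percentage of a reference amount
    (e.g. GDP-man titre against the initial GDP charge)."""
    if reference_amount <= 0:
        raise ValidationError("reference_amount must be > 0")
    return 100.0 * result.final(product) / reference_amount


def steady_rate(
    result: SimulationResult,
    species: str,
    window: tuple[float, float] = (60.0, 240.0),
    lag_tolerance: float = 0.2,
) -> tuple[float, float]:
    """Steady production rate and lag time of ``species``.

    The rate is the ordinary least-squares slope of concentration vs time
    over ``window`` (µM/min). The lag is the earliest time after which the
    local (finite-difference) slope stays within ``lag_tolerance`` (default
    20%) of the window slope; 0 for an exactly linear series.
    """
    t_lo, t_hi = window
    mask = (result.times >= t_lo) & (result.times <= t_hi)
    if mask.sum() < 3:
        raise ValidationError(
            f"need >= 3 sample points inside window {window}, got {int(mask.sum())}"
        )
    t = result.times[mask]
    c = result[species][mask]
    slope_M = float(np.polyfit(t, c, 1)[0])

    local = np.gradient(result[species], result.times)
    upto = result.times <= t_hi
    t_all, local = result.times[upto], local[upto]
    tol = lag_tolerance * abs(slope_M)
    ok = np.abs(local - slope_M) <= tol + 1e-30
    # earliest time from which the local slope stays in band
    lag = float(t_hi)
    for i in range(len(t_all)):
        if ok[i:].all():
            lag = float(t_all[i])
            break
    return slope_M * 1e6, lag


def equilibrium_ratio(
    result: SimulationResult,
    numerator: str | Sequence[str],
    denominator: str | Sequence[str],
    derivative_tol: float = 1e-9,
) -> float:
    """Mass-action ratio prod(numerator)/prod(denominator) at the final time.

    Requires the system to have relaxed: the time derivative of every
    numerator species must be below ``derivative_tol`` mol/(L min), else a
    :class:`ConvergenceError` naming the residual is raised.
    """
    num = (numerator,) if isinstance(numerator, str) else tuple(numerator)
    den = (denominator,) if isinstance(denominator, str) else tuple(denominator)
    y_end = np.maximum(result.concentrations[:, -1], 0.0)
    dy = result.model._S @ result.model._rates_raw(y_end)
    for sp in num:
        residual = abs(float(dy[result.model.species_index(sp)]))
        if residual > derivative_tol:
            raise ConvergenceError(
                f"|d[{sp}]/dt| = {residual:.3g} mol/(L min) exceeds "
                f"{derivative_tol:g}; extend t_end",
                residual=residual,
            )
    den_val = float(np.prod([result.final(sp) for sp in den]))
    if den_val <= 0:
        raise ValidationError(f"denominator {den} is not positive at t_end")
    num_val = float(np.prod([result.final(sp) for sp in num]))
    return num_val / den_val


def time_to_fraction(
    result: SimulationResult, species: str, fraction: float
) -> float:
    """First time (min) at which conversion 1 - [S]/[S]0 reaches ``fraction``
    (linear interpolation between samples); ``inf`` if never reached."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    c = result[species]
    c0 = c[0]
    if c0 <= 0:
        raise ValidationError(f"species {species!r} starts at zero")
    if fraction == 0.0:
        return 0.0
    conv = 1.0 - c / c0
    reached = np.flatnonzero(conv >= fraction)
    if reached.size == 0:
        return float("inf")
    i = int(reached[0])
    if i == 0:
        return float(result.times[0])
    t0, t1 = result.times[i - 1], result.times[i]
    f0, f1 = conv[i - 1], conv[i]
    if f1 == f0:
        return float(t1)
    return float(t0 + (fraction - f0) * (t1 - t0) / (f1 - f0))
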