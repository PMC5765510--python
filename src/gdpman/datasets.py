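"""Synthetic progress-curve datasets with the structure of the study's six
experimental sets.

The raw ion-chromatography data behind the rate constants is not deposited,
so this module generates noisy progress curves from the model itself: a
design library mirrors the six experiment collections (glucokinase 16
reactions, pyrophosphatase 13, polyphosphate kinase 25, ManB/ManC 42,
Alg1 8, multi-enzyme cascade 16), and :func:`generate` simulates a design
and perturbs the sampled concentrations with multiplicative plus additive
Gaussian noise, truncated at zero like a censoring detector.

The generator's defaults define the benchmark conditions for the parameter
recovery studies: 5% relative noise with a 2 µM additive floor, the
conventional precision class of a validated ion-chromatography assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .model import METABOLITES, POLYP, CascadeModel, RateParameters
from .simulate import (
    ExperimentDesign,
    coupled_cascade_design,
    simulate,
    standard_cascade_design,
)

__all__ = [
    "NoiseModel",
    "TimeSeriesDataset",
    "COLLECTION_VARIANTS",
    "study_designs",
    "design_collection",
    "generate",
    "generate_collection",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description: ``cv`` is the fractional multiplicative
    Gaussian scale, ``floor`` an additive Gaussian s.d. in mol/L (detector
    noise floor); draws below zero are truncated to zero."""

    cv: float = 0.05
    floor: float = 2e-6
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0 or self.floor < 0:
            raise ValidationError("noise cv and floor must be >= 0")


@dataclass
class TimeSeriesDataset:
    """Measured or synthetic progress curves for one experiment design.

    ``values`` has shape (n_times, n_species, n_replicates) in mol/L;
    ``generating_parameters`` is the :class:`RateParameters` used for a
    synthetic set, or the string ``"measured"``; ``noise`` likewise is a
    :class:`NoiseModel` or ``"unknown"``.
    """

    design: ExperimentDesign
    variant: str
    times: np.ndarray
    species: tuple[str, ...]
    values: np.ndarray
    generating_parameters: RateParameters | str = "measured"
    noise: NoiseModel | str = "unknown"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.times.size, len(self.species), self.design.replicates)
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != (times, species, "
                f"replicates) = {expected}"
            )
        sample = set(np.round(self.design.sample_times, 9))
        if not set(np.round(self.times, 9)) <= sample:
            raise ValidationError("observation times must be design sample times")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def replicate_mean(self) -> np.ndarray:
        return self.values.mean(axis=2)

    def equals(self, other: "TimeSeriesDataset") -> bool:
        return (
            self.variant == other.variant
            and self.species == other.species
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )


#: which model variant each design collection exercises
COLLECTION_VARIANTS: Mapping[str, str] = {
    "glk": "glk_only",
    "ppa": "ppa_only",
    "ppk2": "ppk2_only",
    "manbc": "manbc_only",
    "alg1": "alg1_only",
    "cascade": "cascade",
}

_MM = 1e-3  # mM -> mol/L

_POLYP0 = 4.0 * _MM * 14  # 4 mM chains of 14 phosphate units


def _design(name, conc_mM, loadings, t_end=240.0, sample_times=None,
            replicates=1, observed=None):
    return ExperimentDesign(
        initial_concentrations={sp: c * _MM for sp, c in conc_mM.items()},
        enzyme_loadings=loadings,
        t_end=t_end,
        sample_times=sample_times,
        replicates=replicates,
        observed_species=observed,
        name=name,
    )


def _glk_designs() -> list[ExperimentDesign]:
    """16 glucokinase reactions: mannose series up to 10 mM at 1.7 mM ATP,
    an ATP series, and a Selwyn loading series (0.5-2 g/L)."""
    obs = ("man6P", "ADP", "ATP")
    designs = []
    for man in (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0):
        designs.append(_design(f"glk_man{man}", {"man": man, "ATP": 1.7},
                               {"glk": 1.0}, t_end=180.0, observed=obs))
    for atp in (0.5, 1.0, 2.0, 3.0):
        designs.append(_design(f"glk_atp{atp}", {"man": 4.0, "ATP": atp},
                               {"glk": 1.0}, t_end=180.0, observed=obs))
    for e in (0.5, 1.0, 2.0):
        designs.append(_design(f"glk_selwyn_e{e}", {"man": 4.0, "ATP": 2.0},
                               {"glk": e}, t_end=180.0, observed=obs))
    designs.append(_design("glk_man10_atp2", {"man": 10.0, "ATP": 2.0},
                           {"glk": 1.0}, t_end=180.0, observed=obs))
    designs.append(_design("glk_man0.25", {"man": 0.25, "ATP": 1.7},
                           {"glk": 1.0}, t_end=180.0, observed=obs))
    return designs


def _ppa_designs() -> list[ExperimentDesign]:
    """13 pyrophosphatase reactions spanning 0.015-0.225 mM pyrophosphate."""
    obs = ("PP", "Pi")
    times = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)
    return [
        _design(f"ppa_pp{pp:.4f}", {"PP": pp}, {"ppa": 0.01},
                t_end=60.0, sample_times=times, observed=obs)
        for pp in np.linspace(0.015, 0.225, 13)
    ]


def _ppk2_designs() -> list[ExperimentDesign]:
    """25 polyphosphate-kinase reactions at the 4 mM PolyP operating point:
    single-nucleotide series, a mixed ADP/GDP grid (the two
    phosphorylations are independent) and a loading series."""
    obs = ("ADP", "ATP", "GDP", "GTP")
    designs = []
    for adp in (0.15, 0.2, 0.3, 0.4, 0.5):
        designs.append(_design(f"ppk2_adp{adp}", {"ADP": adp, POLYP: 56.0},
                               {"ppk2": 0.05}, observed=obs))
    for gdp in (0.15, 0.2, 0.3, 0.4, 0.5):
        designs.append(_design(f"ppk2_gdp{gdp}", {"GDP": gdp, POLYP: 56.0},
                               {"ppk2": 0.05}, observed=obs))
    for adp in (0.15, 0.3, 0.5):
        for gdp in (0.15, 0.3, 0.5):
            designs.append(
                _design(f"ppk2_adp{adp}_gdp{gdp}",
                        {"ADP": adp, "GDP": gdp, POLYP: 56.0},
                        {"ppk2": 0.05}, observed=obs)
            )
    for e in (0.025, 0.05, 0.1):
        designs.append(_design(f"ppk2_e{e}", {"ADP": 0.2, "GDP": 0.2, POLYP: 56.0},
                               {"ppk2": e}, observed=obs))
    for nuc in (0.25, 0.35, 0.45):
        designs.append(_design(f"ppk2_both{nuc}",
                               {"ADP": nuc, "GDP": nuc, POLYP: 56.0},
                               {"ppk2": 0.05}, observed=obs))
    return designs


def _manbc_designs() -> list[ExperimentDesign]:
    """42 ManB/ManC reactions: forward man6P x GTP grids, reverse reactions
    from GDP-man + PP at two loadings, and an enzyme series spanning
    0.086-0.855 g/L (substrates 0.4-1.7 mM)."""
    obs = ("man6P", "GTP", "GDPM", "PP", "Pi")
    designs = []
    grid = (0.4, 0.8, 1.2, 1.7)
    for m6p in grid:
        for gtp in grid:
            designs.append(_design(f"manbc_f_{m6p}_{gtp}",
                                   {"man6P": m6p, "GTP": gtp},
                                   {"manbc": 0.3}, observed=obs))
    for e in (0.171, 0.342):
        designs.append(_design(f"manbc_rev_e{e}",
                               {"GDPM": 1.7, "PP": 1.7},
                               {"manbc": e}, observed=obs))
    for e in (0.086, 0.171, 0.342, 0.513, 0.684, 0.855):
        designs.append(_design(f"manbc_e{e}", {"man6P": 1.0, "GTP": 1.0},
                               {"manbc": e}, observed=obs))
    for m6p in (0.4, 1.7):
        for gtp in (0.6, 1.4):
            designs.append(_design(f"manbc_a_{m6p}_{gtp}",
                                   {"man6P": m6p, "GTP": gtp},
                                   {"manbc": 0.171}, observed=obs))
    for gdpm in (0.8, 1.7):
        for pp in (0.8, 1.7):
            designs.append(_design(f"manbc_r_{gdpm}_{pp}",
                                   {"GDPM": gdpm, "PP": pp},
                                   {"manbc": 0.171}, observed=obs))
    for i, m6p in enumerate((0.5, 0.62, 0.74, 0.86, 0.98, 1.1, 1.22, 1.34,
                             1.46, 1.58)):
        designs.append(_design(f"manbc_s{i}", {"man6P": m6p, "GTP": 1.2},
                               {"manbc": 0.3}, observed=obs))
    return designs


def _alg1_designs() -> list[ExperimentDesign]:
    """8 mannosyltransferase reactions around 1.5 mM GDP-man / 0.7 mM
    acceptor at 0.07-0.1 g/L enzyme."""
    obs = ("GDPM", "GDP", "Man1")
    times = (0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)
    designs = []
    for gdpm in (1.5, 1.0):
        for phyt in (0.7, 0.35):
            for e in (0.07, 0.1):
                designs.append(
                    _design(f"alg1_{gdpm}_{phyt}_e{e}",
                            {"GDPM": gdpm, "Phyt": phyt}, {"alg1": e},
                            t_end=60.0, sample_times=times, observed=obs)
                )
    return designs


def _cascade_designs() -> list[ExperimentDesign]:
    """16 multi-enzyme cascade reactions: the standard run plus initial-
    concentration variations, four replicates each."""
    designs = [standard_cascade_design()]
    for man in (6.0, 3.0, 1.5, 9.0):
        for gdp in (0.8, 0.4):
            for adp in (0.8, 0.4):
                if (man, gdp, adp) == (6.0, 0.8, 0.8):
                    continue  # the standard design, already first
                designs.append(
                    standard_cascade_design(
                        initial_concentrations={
                            "man": man * _MM,
                            "GDP": gdp * _MM,
                            "ADP": adp * _MM,
                            POLYP: _POLYP0,
                        },
                        name=f"cascade_man{man}_gdp{gdp}_adp{adp}",
                    )
                )
    return designs


def study_designs() -> dict[str, list[ExperimentDesign]]:
    """The six design collections (16 + 13 + 25 + 42 + 8 + 16 = 120
    experiment designs), keyed ``glk``, ``ppa``, ``ppk2``, ``manbc``,
    ``alg1``, ``cascade``. The exact grids of the single-enzyme experiments
    are representative spans of the reported concentration ranges, not
    reconstructions of unpublished protocols."""
    return {
        "glk": _glk_designs(),
        "ppa": _ppa_designs(),
        "ppk2": _ppk2_designs(),
        "manbc": _manbc_designs(),
        "alg1": _alg1_designs(),
        "cascade": _cascade_designs(),
    }


def design_collection(name: str) -> list[ExperimentDesign]:
    try:
        return study_designs()[name]
    except KeyError:
        raise ValidationError(
            f"unknown collection {name!r}; expected one of "
            f"{sorted(COLLECTION_VARIANTS)}"
        ) from None


def generate(
    design: ExperimentDesign,
    variant: str,
    parameters: RateParameters | None = None,
    noise: NoiseModel | None = None,
    ppa_mode: str = "fast_kinetic",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeSeriesDataset:
    """Simulate ``design`` under ``variant`` and perturb the sampled
    concentrations replicate-wise: c * (1 + N(0, cv)) + N(0, floor),
    truncated at zero. Fully reproducible from ``noise.seed``."""
    parameters = parameters if parameters is not None else RateParameters()
    noise = noise if noise is not None else NoiseModel()
    model = CascadeModel(variant, parameters, ppa_mode)
    result = simulate(model, design, rtol=rtol, atol=atol,
                      t_eval=design.sample_times)
    species = design.observed()
    clean = result.sampled(species, design.sample_times)  # times x species
    rng = np.random.default_rng(noise.seed)
    shape = clean.shape + (design.replicates,)
    values = clean[:, :, None] * (1.0 + noise.cv * rng.standard_normal(shape))
    values = values + noise.floor * rng.standard_normal(shape)
    np.maximum(values, 0.0, out=values)
    return TimeSeriesDataset(
        design=design,
        variant=variant,
        times=np.asarray(design.sample_times),
        species=tuple(species),
        values=values,
        generating_parameters=parameters,
        noise=noise,
    )


def generate_collection(
    name: str,
    parameters: RateParameters | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    ppa_mode: str = "fast_kinetic",
) -> list[TimeSeriesDataset]:
    """Generate every design of a collection; per-design seeds are derived
    deterministically from ``seed`` (or from ``noise.seed``)."""
    base = noise if noise is not None else NoiseModel()
    root = base.seed if seed is None else int(seed)
    designs = design_collection(name)
    child_seeds = np.random.default_rng(root).integers(2**31, size=len(designs))
    variant = COLLECTION_VARIANTS[name]
    return [
        generate(
            design,
            variant,
            parameters=parameters,
            noise=NoiseModel(cv=base.cv, floor=base.floor, seed=int(s)),
            ppa_mode=ppa_mode,
        )
        for design, s in zip(designs, child_seeds)
    ]


def coupled_cascade_dataset(
    parameters: RateParameters | None = None,
    noise: NoiseModel | None = None,
) -> TimeSeriesDataset:
    """Synthetic fixture for the Alg1-coupled cascade (three replicates),
    generated with the kinase-refit constants by default."""
    params = (
        parameters
        if parameters is not None
        else RateParameters().with_cascade_refit()
    )
    return generate(coupled_cascade_design(), "cascade_alg1",
                    parameters=params, noise=noise)
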