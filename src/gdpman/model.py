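"""Reaction network and mass-action rate laws of the GDP-mannose cascade.

The model describes a cell-free enzyme cascade that synthesises and
regenerates the nucleotide sugar GDP-mannose from mannose and inorganic
polyphosphate, using catalytic amounts of ADP and GDP:

* glucokinase (``glk``) phosphorylates mannose with ATP to mannose-6-phosphate
  (irreversible bimolecular mass action, reaction ``r1``);
* 1-domain polyphosphate kinase 2 (``ppk2``) reversibly phosphorylates GDP and
  ADP from polyphosphate (linear reversible mass action, ``r2``/``r3``); the
  two phosphorylations are kinetically independent at the 4 mM polyphosphate
  operating point the model is parameterised for;
* the phosphomannomutase / mannose-1-phosphate-guanylyltransferase complex
  (``manbc``) is lumped into one reversible reaction
  man6P + GTP <-> GDP-man + PP (``r4``) plus a slow pyrophosphate-cleaving
  side activity (``r5``);
* inorganic pyrophosphatase (``ppa``) hydrolyses pyrophosphate to
  2 phosphate, pulling GDP-man formation forward. Its turnover per enzyme
  mass is so fast that it is treated either as a fast first-order reaction
  (``r7``, the default) or as a strictly instantaneous conversion (``r6``,
  an algebraic elimination of PP); see ``ppa_mode``;
* optionally, the mannosyltransferase Alg1(dTM) transfers mannose from
  GDP-man onto the lipid acceptor phytanyl-PP-(GlcNAc)2 (``rALG1``), with a
  squared-concentration empirical rate law.

Units: metabolite concentrations are mol/L, enzyme loadings g/L, time
minutes. Polyphosphate is a bookkeeping pool in phosphate-equivalents that
is depleted by kinase turnover but does not enter any rate law (the rate
constants are only valid at the 4 mM PolyP14 operating point).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, ConsistencyError, ValidationError

__all__ = [
    "METABOLITES",
    "POLYP",
    "ENZYMES",
    "SPECIES_ORDER",
    "MOIETY_POOLS",
    "VARIANTS",
    "Species",
    "RateParameters",
    "Reaction",
    "CascadeModel",
    "build_model",
    "rate_vector",
    "ode_rhs",
    "conservation_pools",
]

logger = logging.getLogger(__name__)

#: measurable metabolites, in canonical state order (mol/L)
METABOLITES = (
    "man", "ATP", "ADP", "GTP", "GDP",
    "man6P", "GDPM", "PP", "Pi", "Phyt", "Man1",
)
#: polyphosphate bookkeeping pool (phosphate-equivalents, mol/L)
POLYP = "PolyP"
#: enzymes, carried in the state vector with zero derivative (g/L)
ENZYMES = ("glk", "ppk2", "manbc", "ppa", "alg1")
#: full state ordering shared by every model variant
SPECIES_ORDER = METABOLITES + (POLYP,) + ENZYMES

#: moiety content per species; each reaction must conserve every pool
MOIETY_POOLS: Mapping[str, Mapping[str, int]] = {
    "adenine": {"ATP": 1, "ADP": 1},
    "guanine": {"GTP": 1, "GDP": 1, "GDPM": 1},
    "mannose": {"man": 1, "man6P": 1, "GDPM": 1, "Man1": 1},
    "lipid": {"Phyt": 1, "Man1": 1},
}


@dataclass(frozen=True)
class Species:
    """One chemical species of the network.

    ``role`` is ``metabolite`` (mol/L), ``enzyme`` (g/L) or ``bookkeeping``
    (the polyphosphate phosphate-equivalent pool).
    """

    name: str
    role: str
    unit: str


def _default_species() -> tuple[Species, ...]:
    out = [Species(n, "metabolite", "mol/L") for n in METABOLITES]
    out.append(Species(POLYP, "bookkeeping", "mol/L phosphate-equivalents"))
    out.extend(Species(n, "enzyme", "g/L") for n in ENZYMES)
    return tuple(out)


@dataclass(frozen=True)
class RateParameters:
    """Mass-action rate constants and equilibrium constants of the cascade.

    Defaults are the constants estimated from the single-enzyme
    progress-curve experiments. The ``*_opt`` alternates are the cascade-refit
    variants: ``k4_opt`` from refitting the lumped GDP-man synthesis constant
    against multi-enzyme data, ``k2_opt``/``k3_opt`` from refitting the
    nucleotide-kinase constants against the Alg1-coupled cascade (where
    nucleoside diphosphate conversion appears inhibited).

    Units: k1, k4 in L^2/(min g mol); k2, k3, k5, k6 in L/(min g);
    k7 in L^4/(min g mol^3); Keq1..Keq3 dimensionless (Keq3 on the mol/L
    mass-action scale). All constants must be strictly positive.
    """

    k1: float = 11.320
    k2: float = 0.519
    Keq1: float = 2.289
    k3: float = 0.439
    Keq2: float = 1.816
    k4: float = 18.163
    Keq3: float = 0.032
    k5: float = 0.130
    k6: float = 13.152
    k7: float = 8.1e9
    k4_opt: float = 4.6e-3
    k2_opt: float = 0.097
    k3_opt: float = 0.041

    def __post_init__(self):
        for name, value in self.as_dict().items():
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"rate parameter {name!r} must be strictly positive and "
                    f"finite, got {value!r}"
                )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def replace(self, **updates: float) -> "RateParameters":
        """Return a copy with the given constants replaced."""
        unknown = set(updates) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigurationError(f"unknown rate parameters: {sorted(unknown)}")
        return dataclasses.replace(self, **updates)

    def with_cascade_refit(self) -> "RateParameters":
        """Constants with the coupled-cascade kinase refit (k2, k3 -> *_opt)."""
        return self.replace(k2=self.k2_opt, k3=self.k3_opt)


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: id, catalysing enzyme, rate-law kind and
    signed stoichiometry (forward = left-to-right as written)."""

    id: str
    enzyme: str
    rate_law: str
    stoichiometry: Mapping[str, int]
    equation: str


_REACTIONS: dict[str, Reaction] = {
    r.id: r
    for r in (
        Reaction(
            "r1", "glk", "irreversible_bimolecular",
            {"man": -1, "ATP": -1, "man6P": +1, "ADP": +1},
            "man + ATP -> man6P + ADP",
        ),
        Reaction(
            "r2", "ppk2", "reversible_linear",
            {"GDP": -1, "GTP": +1, POLYP: -1},
            "PolyP(n) + GDP <-> PolyP(n-1) + GTP",
        ),
        Reaction(
            "r3", "ppk2", "reversible_linear",
            {"ADP": -1, "ATP": +1, POLYP: -1},
            "PolyP(n) + ADP <-> PolyP(n-1) + ATP",
        ),
        Reaction(
            "r4", "manbc", "reversible_bimolecular",
            {"man6P": -1, "GTP": -1, "GDPM": +1, "PP": +1},
            "man6P + GTP <-> GDP-man + PP",
        ),
        Reaction(
            "r5", "manbc", "first_order",
            {"PP": -1, "Pi": +2},
            "PP + H2O -> 2 Pi (ManB/ManC side activity)",
        ),
        Reaction(
            "r6", "ppa", "instant_hydrolysis",
            {"PP": -1, "Pi": +2},
            "PP + H2O -> 2 Pi (instantaneous channel)",
        ),
        Reaction(
            "r7", "ppa", "first_order",
            {"PP": -1, "Pi": +2},
            "PP + H2O -> 2 Pi",
        ),
        Reaction(
            "rALG1", "alg1", "squared_bimolecular",
            {"GDPM": -1, "Phyt": -1, "Man1": +1, "GDP": +1},
            "phyt-PP-(GlcNAc)2 + GDP-man -> phyt-PP-(GlcNAc)2-Man1 + GDP",
        ),
    )
}

#: reaction sets of the buildable model variants; the cascade is the sum of
#: the single-enzyme systems, and the coupled cascade adds the Alg1 reaction
VARIANTS: Mapping[str, tuple[str, ...]] = {
    "glk_only": ("r1",),
    "ppk2_only": ("r2", "r3"),
    "manbc_only": ("r4", "r5"),
    "ppa_only": ("r6", "r7"),
    "alg1_only": ("rALG1",),
    "cascade": ("r1", "r2", "r3", "r4", "r5", "r6", "r7"),
    "cascade_alg1": ("r1", "r2", "r3", "r4", "r5", "r6", "r7", "rALG1"),
}

_PPA_MODES = ("fast_kinetic", "strict_instant")

_IX = {name: i for i, name in enumerate(SPECIES_ORDER)}


def _check_moiety_balance(reaction: Reaction) -> None:
    for pool, content in MOIETY_POOLS.items():
        total = sum(
            coeff * content.get(sp, 0)
            for sp, coeff in reaction.stoichiometry.items()
        )
        if total != 0:
            raise ConsistencyError(  # pragma: no cover - guards the registry
                f"reaction {reaction.id} does not conserve the {pool} pool"
            )


class CascadeModel:
    """Executable form of the cascade reaction network.

    Parameters
    ----------
    variant : str
        One of :data:`VARIANTS`: a single-enzyme subsystem, the full
        GDP-mannose ``cascade`` (r1-r7) or the Alg1-coupled ``cascade_alg1``.
    parameters : RateParameters, optional
        Rate constants; defaults to the estimated single-enzyme constants.
    ppa_mode : {"fast_kinetic", "strict_instant"}
        How the pyrophosphatase is realised. ``fast_kinetic`` (default) uses
        the fast first-order law ``r7``; ``strict_instant`` eliminates PP
        algebraically: any PP made by ``r4`` is routed straight to phosphate
        through channel ``r6`` and PP stays identically zero.
    disabled_reactions : iterable of str, optional
        Reaction ids removed from the variant's set (e.g. disable the ManB/C
        side hydrolysis ``r5`` to study the pure reversible equilibrium).

    All variants share the full state vector (metabolites + PolyP pool +
    enzyme loadings) so that nested variants integrate on identical state
    spaces; only the reaction set differs.
    """

    def __init__(
        self,
        variant: str = "cascade",
        parameters: RateParameters | None = None,
        ppa_mode: str = "fast_kinetic",
        disabled_reactions: Iterable[str] = (),
    ):
        if variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown model variant {variant!r}; expected one of "
                f"{sorted(VARIANTS)}"
            )
        if ppa_mode not in _PPA_MODES:
            raise ConfigurationError(
                f"unknown ppa_mode {ppa_mode!r}; expected one of {_PPA_MODES}"
            )
        disabled = set(disabled_reactions)
        unknown = disabled - set(_REACTIONS)
        if unknown:
            raise ConfigurationError(f"unknown reaction ids: {sorted(unknown)}")
        self.variant = variant
        self.parameters = parameters if parameters is not None else RateParameters()
        self.ppa_mode = ppa_mode
        self.species: tuple[Species, ...] = _default_species()
        self.reactions: tuple[Reaction, ...] = tuple(
            _REACTIONS[rid] for rid in VARIANTS[variant] if rid not in disabled
        )
        self.reaction_ids: tuple[str, ...] = tuple(r.id for r in self.reactions)
        for rxn in self.reactions:
            _check_moiety_balance(rxn)
        # stoichiometry matrix, species x reactions
        S = np.zeros((len(SPECIES_ORDER), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sp, coeff in rxn.stoichiometry.items():
                S[_IX[sp], j] = coeff
        self._S = S
        self._has = {rid: (rid in self.reaction_ids) for rid in _REACTIONS}

    # -- introspection ---------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return SPECIES_ORDER

    @property
    def n_species(self) -> int:
        return len(SPECIES_ORDER)

    def species_index(self, name: str) -> int:
        try:
            return _IX[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        """Copy of the species x reactions stoichiometry matrix."""
        return self._S.copy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CascadeModel(variant={self.variant!r}, "
            f"reactions={list(self.reaction_ids)}, ppa_mode={self.ppa_mode!r})"
        )

    # -- state handling --------------------------------------------------

    def state_vector(self, state: Mapping[str, float] | np.ndarray) -> np.ndarray:
        """Coerce a name->value mapping (or an ordered array) to the canonical
        state vector; unreferenced species default to zero."""
        if isinstance(state, Mapping):
            unknown = set(state) - set(SPECIES_ORDER)
            if unknown:
                raise KeyError(f"unknown species in state: {sorted(unknown)}")
            y = np.zeros(len(SPECIES_ORDER))
            for name, value in state.items():
                y[_IX[name]] = value
            return y
        y = np.asarray(state, dtype=float)
        if y.shape != (len(SPECIES_ORDER),):
            raise ValidationError(
                f"state vector must have length {len(SPECIES_ORDER)}, "
                f"got shape {y.shape}"
            )
        return y.copy()

    # -- kinetics --------------------------------------------------------

    def _rates_raw(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction rates (mol/(L min)) for a clipped state vector."""
        p = self.parameters
        ix = _IX
        e_glk = y[ix["glk"]]
        e_pk2 = y[ix["ppk2"]]
        e_man = y[ix["manbc"]]
        e_ppa = y[ix["ppa"]]
        e_alg = y[ix["alg1"]]
        strict = self.ppa_mode == "strict_instant"

        rates = np.empty(len(self.reactions))
        r4_value = 0.0
        for j, rxn in enumerate(self.reactions):
            rid = rxn.id
            if rid == "r1":
                r = p.k1 * e_glk * y[ix["man"]] * y[ix["ATP"]]
            elif rid == "r2":
                r = p.k2 * e_pk2 * (y[ix["GDP"]] - y[ix["GTP"]] / p.Keq1)
            elif rid == "r3":
                r = p.k3 * e_pk2 * (y[ix["ADP"]] - y[ix["ATP"]] / p.Keq2)
            elif rid == "r4":
                r = p.k4 * e_man * (
                    y[ix["man6P"]] * y[ix["GTP"]]
                    - y[ix["PP"]] * y[ix["GDPM"]] / p.Keq3
                )
                r4_value = r
            elif rid == "r5":
                r = p.k5 * e_man * y[ix["PP"]]
            elif rid == "r6":
                # strict-instant channel: consume PP exactly as fast as r4
                # makes it, keeping [PP] identically zero. Inactive in
                # fast-kinetic mode.
                r = max(r4_value, 0.0) if strict else 0.0
            elif rid == "r7":
                r = 0.0 if strict else p.k6 * e_ppa * y[ix["PP"]]
            elif rid == "rALG1":
                r = p.k7 * e_alg * y[ix["GDPM"]] ** 2 * y[ix["Phyt"]] ** 2
            else:  # pragma: no cover
                raise ConfigurationError(f"unhandled reaction {rid!r}")
            rates[j] = r
        return rates

    def rate_vector(self, state) -> np.ndarray:
        """Per-reaction rates at ``state``, in mol/(L min).

        The sign convention is forward = left-to-right as the reactions are
        written; reversible rates go negative past their equilibrium.
        Raises :class:`ValidationError` on negative concentrations.
        """
        y = self.state_vector(state)
        if np.any(y < 0):
            bad = [SPECIES_ORDER[i] for i in np.flatnonzero(y < 0)]
            raise ValidationError(f"negative concentrations for {bad}")
        return self._rates_raw(y)

    def ode_rhs(self, state) -> np.ndarray:
        """Time derivative d(state)/dt = S . r, mol/(L min).

        Enzyme entries have zero derivative; the PolyP pool loses one
        phosphate-equivalent per net kinase turnover and feeds back into no
        rate.
        """
        y = self.state_vector(state)
        if np.any(y < 0):
            bad = [SPECIES_ORDER[i] for i in np.flatnonzero(y < 0)]
            raise ValidationError(f"negative concentrations for {bad}")
        return self._S @ self._rates_raw(y)

    def make_rhs(self, enzyme_decay_rates: Mapping[str, float] | None = None):
        """Build a ``f(t, y)`` right-hand side for the integrator.

        Concentrations are clipped at zero inside the rate evaluation only
        (the raw solver state is untouched) and clip events are counted in
        the returned mutable ``info`` dict. ``enzyme_decay_rates`` maps an
        enzyme name to a first-order inactivation rate (1/min), used by the
        Selwyn-test oracle for deliberately unstable enzymes.
        """
        S = self._S
        n_meta = len(METABOLITES) + 1  # metabolites + PolyP block
        info = {"clip_events": 0}
        decay_idx = np.array([], dtype=int)
        decay_lam = np.array([])
        if enzyme_decay_rates:
            unknown = set(enzyme_decay_rates) - set(ENZYMES)
            if unknown:
                raise ConfigurationError(f"unknown enzymes: {sorted(unknown)}")
            decay_idx = np.array([_IX[e] for e in enzyme_decay_rates])
            decay_lam = np.array([float(v) for v in enzyme_decay_rates.values()])

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            yc = y
            if np.any(y[:n_meta] < 0.0):
                info["clip_events"] += 1
                yc = y.copy()
                np.maximum(yc[:n_meta], 0.0, out=yc[:n_meta])
            dy = S @ self._rates_raw(yc)
            if decay_idx.size:
                dy[decay_idx] = -decay_lam * y[decay_idx]
            return dy

        return rhs, info

    # -- conservation ----------------------------------------------------

    def conservation_pools(self, state) -> dict[str, float]:
        """Moiety pool totals (mol/L): adenine = ATP+ADP; guanine =
        GDP+GTP+GDP-man+Man1; mannose = man+man6P+GDP-man+Man1; lipid =
        Phyt+Man1. Each is invariant under the network stoichiometry."""
        y = self.state_vector(state)
        return {
            pool: float(sum(coeff * y[_IX[sp]] for sp, coeff in content.items()))
            for pool, content in MOIETY_POOLS.items()
        }


# -- module-level convenience functions ----------------------------------


def build_model(
    variant: str,
    parameters: RateParameters | None = None,
    ppa_mode: str = "fast_kinetic",
    disabled_reactions: Iterable[str] = (),
) -> CascadeModel:
    """Build a :class:`CascadeModel` for the requested variant."""
    return CascadeModel(variant, parameters, ppa_mode, disabled_reactions)


def rate_vector(model: CascadeModel, state) -> np.ndarray:
    return model.rate_vector(state)


def ode_rhs(model: CascadeModel, state) -> np.ndarray:
    return model.ode_rhs(state)


def conservation_pools(model: CascadeModel, state) -> dict[str, float]:
    return model.conservation_pools(state)
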