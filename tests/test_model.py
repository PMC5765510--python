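"""Unit and property tests for the reaction network and rate laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdpman import (
    METABOLITES,
    POLYP,
    SPECIES_ORDER,
    VARIANTS,
    CascadeModel,
    ConfigurationError,
    RateParameters,
    ValidationError,
    build_model,
)
from gdpman.model import MOIETY_POOLS


class TestBuildModel:
    @pytest.mark.parametrize(
        "variant, expected",
        [
            ("glk_only", ("r1",)),
            ("ppk2_only", ("r2", "r3")),
            ("manbc_only", ("r4", "r5")),
            ("ppa_only", ("r6", "r7")),
            ("alg1_only", ("rALG1",)),
            ("cascade", ("r1", "r2", "r3", "r4", "r5", "r6", "r7")),
        ],
    )
    def test_variant_reaction_sets(self, variant, expected):
        assert build_model(variant).reaction_ids == expected

    def test_cascade_nesting(self):
        """The coupled model contains the cascade, which contains every
        single-enzyme reaction set."""
        coupled = set(build_model("cascade_alg1").reaction_ids)
        cascade = set(build_model("cascade").reaction_ids)
        assert cascade < coupled
        for variant in ("glk_only", "ppk2_only", "manbc_only", "ppa_only"):
            assert set(build_model(variant).reaction_ids) <= cascade
        assert set(build_model("alg1_only").reaction_ids) <= coupled

    def test_unknown_variant_raises(self):
        with pytest.raises(ConfigurationError):
            build_model("hexokinase_only")

    def test_unknown_ppa_mode_raises(self):
        with pytest.raises(ConfigurationError):
            build_model("cascade", ppa_mode="adiabatic")

    def test_nonpositive_parameter_raises(self):
        with pytest.raises(ValidationError):
            RateParameters(k1=0.0)
        with pytest.raises(ValidationError):
            RateParameters(Keq1=-2.0)

    def test_disabled_reactions(self):
        model = build_model("manbc_only", disabled_reactions=("r5",))
        assert model.reaction_ids == ("r4",)
        with pytest.raises(ConfigurationError):
            build_model("cascade", disabled_reactions=("r99",))

    def test_state_dimension_equals_species_count(self):
        model = build_model("cascade_alg1")
        assert model.n_species == len(model.species) == len(SPECIES_ORDER)


class TestStoichiometry:
    def test_every_reaction_conserves_every_moiety_pool(self):
        model = build_model("cascade_alg1")
        S = model.stoichiometry_matrix
        for pool, content in MOIETY_POOLS.items():
            weights = np.array(
                [content.get(sp, 0) for sp in model.species_names]
            )
            np.testing.assert_array_equal(
                weights @ S, np.zeros(S.shape[1]), err_msg=pool
            )

    def test_polyp_decrements_per_kinase_turnover(self):
        model = build_model("cascade")
        S = model.stoichiometry_matrix
        i = model.species_index(POLYP)
        for rid, coeff in zip(model.reaction_ids, S[i]):
            assert coeff == (-1 if rid in ("r2", "r3") else 0)


def _brute_force_rates(params, y, ix, reaction_ids, strict=False):
    """Independent re-evaluation of each printed rate law, term by term."""
    e = {n: y[ix[n]] for n in ("glk", "ppk2", "manbc", "ppa", "alg1")}
    c = {n: y[ix[n]] for n in METABOLITES}
    laws = {
        "r1": params.k1 * e["glk"] * c["man"] * c["ATP"],
        "r2": params.k2 * e["ppk2"] * (c["GDP"] - c["GTP"] / params.Keq1),
        "r3": params.k3 * e["ppk2"] * (c["ADP"] - c["ATP"] / params.Keq2),
        "r4": params.k4
        * e["manbc"]
        * (c["man6P"] * c["GTP"] - c["PP"] * c["GDPM"] / params.Keq3),
        "r5": params.k5 * e["manbc"] * c["PP"],
        "r7": 0.0 if strict else params.k6 * e["ppa"] * c["PP"],
        "rALG1": params.k7 * e["alg1"] * c["GDPM"] ** 2 * c["Phyt"] ** 2,
    }
    laws["r6"] = max(laws["r4"], 0.0) if strict else 0.0
    return np.array([laws[rid] for rid in reaction_ids])


class TestRateVector:
    def test_glucokinase_rate_arithmetic(self):
        """k1 * e * [man] * [ATP] evaluated at 1 g/L, 4 mM, 2 mM."""
        model = build_model("glk_only")
        rates = model.rate_vector(
            {"man": 4e-3, "ATP": 2e-3, "glk": 1.0}
        )
        assert rates == pytest.approx([11.320 * 1.0 * 4e-3 * 2e-3])
        assert rates == pytest.approx([9.056e-5])

    def test_reversible_law_vanishes_at_equilibrium(self):
        model = build_model("ppk2_only")
        state = {"GDP": 1e-4, "GTP": 2.289e-4, "ppk2": 0.05}
        rates = model.rate_vector(state)
        assert rates[0] == pytest.approx(0.0, abs=1e-18)

    def test_mannosyltransferase_squared_law(self):
        model = build_model("alg1_only")
        rates = model.rate_vector(
            {"GDPM": 1.5e-3, "Phyt": 0.7e-3, "alg1": 0.1}
        )
        expected = 8.1e9 * 0.1 * (1.5e-3) ** 2 * (0.7e-3) ** 2
        assert rates == pytest.approx([expected])
        assert expected == pytest.approx(8.93e-4, rel=1e-3)

    @pytest.mark.parametrize("ppa_mode", ["fast_kinetic", "strict_instant"])
    def test_matches_bruteforce_on_random_states(self, rng, ppa_mode):
        """The compiled rate vector agrees with a term-by-term independent
        re-evaluation of every printed law on 100 random states."""
        model = build_model("cascade_alg1", ppa_mode=ppa_mode)
        ix = {n: model.species_index(n) for n in SPECIES_ORDER}
        for _ in range(100):
            y = rng.random(model.n_species) * 1e-2
            expected = _brute_force_rates(
                model.parameters, y, ix, model.reaction_ids,
                strict=(ppa_mode == "strict_instant"),
            )
            np.testing.assert_allclose(
                model.rate_vector(y), expected, rtol=1e-12, atol=0
            )

    def test_negative_concentration_raises(self):
        model = build_model("glk_only")
        with pytest.raises(ValidationError):
            model.rate_vector({"man": -1e-5, "ATP": 1e-3, "glk": 1.0})

    @given(
        gdp=st.floats(1e-6, 1e-2),
        gtp=st.floats(0.0, 1e-2),
        e=st.floats(1e-3, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kinase_law_is_odd_around_equilibrium(self, gdp, gtp, e):
        """Reflecting (GDP, GTP) componentwise through the equilibrium point
        of their conserved total flips the GDP-phosphorylation rate sign
        exactly."""
        model = build_model("ppk2_only")
        K = model.parameters.Keq1
        total = gdp + gtp
        eq = (total / (1 + K), total * K / (1 + K))
        r = model.rate_vector({"GDP": gdp, "GTP": gtp, "ppk2": e})[0]
        reflected = (2 * eq[0] - gdp, 2 * eq[1] - gtp)
        if reflected[0] < 0 or reflected[1] < 0:
            return
        r_ref = model.rate_vector(
            {"GDP": reflected[0], "GTP": reflected[1], "ppk2": e}
        )[0]
        assert r_ref == pytest.approx(-r, abs=1e-16 + 1e-9 * abs(r))


class TestOdeRhs:
    def test_zero_state_has_zero_derivative(self):
        model = build_model("cascade_alg1")
        np.testing.assert_array_equal(
            model.ode_rhs(np.zeros(model.n_species)), 0.0
        )

    def test_nucleotide_balance_couples_r1_and_r3(self, rng):
        """d[ATP]/dt = r3 - r1 and d[ADP]/dt = r1 - r3 in the cascade."""
        model = build_model("cascade")
        y = rng.random(model.n_species) * 1e-3
        rates = dict(zip(model.reaction_ids, model.rate_vector(y)))
        dy = model.ode_rhs(y)
        assert dy[model.species_index("ATP")] == pytest.approx(
            rates["r3"] - rates["r1"]
        )
        assert dy[model.species_index("ADP")] == pytest.approx(
            rates["r1"] - rates["r3"]
        )

    def test_phosphate_release_is_twice_hydrolysis_flux(self, rng):
        model = build_model("cascade")
        y = rng.random(model.n_species) * 1e-3
        rates = dict(zip(model.reaction_ids, model.rate_vector(y)))
        dy = model.ode_rhs(y)
        assert dy[model.species_index("Pi")] == pytest.approx(
            2.0 * (rates["r5"] + rates["r6"] + rates["r7"])
        )

    def test_enzymes_have_zero_derivative(self, rng):
        model = build_model("cascade_alg1")
        y = rng.random(model.n_species) * 1e-3
        dy = model.ode_rhs(y)
        for enz in ("glk", "ppk2", "manbc", "ppa", "alg1"):
            assert dy[model.species_index(enz)] == 0.0


class TestConservationPools:
    def test_standard_start_pool_totals(self, cascade_model, standard_design):
        state = standard_design.initial_state(cascade_model)
        pools = cascade_model.conservation_pools(state)
        assert pools["adenine"] == pytest.approx(8e-4)
        assert pools["guanine"] == pytest.approx(8e-4)
        assert pools["mannose"] == pytest.approx(6e-3)
        assert pools["lipid"] == 0.0

    def test_lipid_pool_bounds_product(self):
        """After deep conversion the lipid pool is unchanged and the product
        cannot exceed the initial acceptor charge."""
        from gdpman import ExperimentDesign, simulate

        model = build_model("alg1_only")
        design = ExperimentDesign(
            {"GDPM": 1.5e-3, "Phyt": 0.7e-3}, {"alg1": 0.1}, t_end=240.0
        )
        result = simulate(model, design)
        pools = model.conservation_pools(result.concentrations[:, -1])
        assert pools["lipid"] == pytest.approx(0.7e-3, rel=1e-9)
        assert result.final("Man1") <= 0.7e-3 * (1 + 1e-12)
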