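"""Simulator and observable tests: analytic relaxation oracles, equilibrium
ratios forced by the rate laws, nesting/consistency invariants and the
observable arithmetic."""

import numpy as np
import pytest

from gdpman import (
    ConvergenceError,
    ExperimentDesign,
    RateParameters,
    SimulationResult,
    ValidationError,
    build_model,
    coupled_cascade_design,
    equilibrium_ratio,
    simulate,
    standard_cascade_design,
    steady_rate,
    time_to_fraction,
    yield_vs_reference,
)

POLYP0 = {"PolyP": 56e-3}


def ppk2_design(t_end=1500.0, **conc):
    conc = {k: v for k, v in conc.items()}
    conc.update(POLYP0)
    return ExperimentDesign(conc, {"ppk2": 0.05}, t_end=t_end,
                            sample_times=(0.0, t_end))


class TestSimulate:
    def test_no_enzyme_no_change(self):
        model = build_model("cascade")
        design = standard_cascade_design(enzyme_loadings={})
        result = simulate(model, design)
        for sp in ("man", "ADP", "GDP"):
            np.testing.assert_allclose(
                result[sp], result[sp][0], rtol=1e-12
            )

    def test_kinase_relaxation_matches_closed_form(self):
        """The isolated reversible phosphorylation follows
        x(t) = x_eq + (x0 - x_eq) exp(-k e (1 + 1/Keq) t) exactly."""
        p = RateParameters()
        model = build_model("ppk2_only", p)
        x0 = 0.2e-3
        design = ExperimentDesign(
            dict(GDP=x0, **POLYP0), {"ppk2": 0.05}, t_end=120.0
        )
        result = simulate(model, design, rtol=1e-10, atol=1e-14)
        x_eq = x0 * p.Keq1 / (1 + p.Keq1)
        lam = p.k2 * 0.05 * (1 + 1 / p.Keq1)
        analytic = x_eq - x_eq * np.exp(-lam * result.times)
        np.testing.assert_allclose(result["GTP"], analytic, rtol=1e-6,
                                   atol=1e-6 * x_eq)

    def test_gdp_equilibrium_ratio(self):
        result = simulate(build_model("ppk2_only"), ppk2_design(GDP=0.2e-3))
        assert equilibrium_ratio(result, "GTP", "GDP") == pytest.approx(
            2.289, rel=1e-3
        )
        # closed-form equilibrium concentration x0 * K / (1 + K)
        assert result.final("GTP") == pytest.approx(
            0.2e-3 * 2.289 / 3.289, rel=1e-6
        )

    def test_adp_equilibrium_ratio(self):
        result = simulate(build_model("ppk2_only"), ppk2_design(ADP=0.2e-3))
        assert equilibrium_ratio(result, "ATP", "ADP") == pytest.approx(
            1.816, rel=1e-3
        )

    def test_equilibrium_ratio_requires_convergence(self):
        result = simulate(
            build_model("ppk2_only"), ppk2_design(GDP=0.2e-3, t_end=5.0)
        )
        with pytest.raises(ConvergenceError):
            equilibrium_ratio(result, "GTP", "GDP")

    def test_coupled_model_with_zero_alg1_reproduces_cascade_bitwise(
        self, cascade_result, standard_design
    ):
        coupled = simulate(build_model("cascade_alg1"), standard_design)
        assert np.array_equal(
            coupled.concentrations, cascade_result.concentrations
        )

    def test_product_is_nondecreasing(self):
        """Man1 is produced by a single irreversible reaction."""
        model = build_model(
            "cascade_alg1", RateParameters().with_cascade_refit()
        )
        result = simulate(model, coupled_cascade_design())
        assert np.all(np.diff(result["Man1"]) >= -1e-15)

    def test_integration_converged_in_tolerance(
        self, cascade_model, standard_design, cascade_result
    ):
        """Halving the tolerances moves [GDP-man](240) by < 0.01%."""
        tight = simulate(cascade_model, standard_design,
                         rtol=0.5e-8, atol=0.5e-12)
        assert tight.final("GDPM") == pytest.approx(
            cascade_result.final("GDPM"), rel=1e-4
        )

    def test_strict_instant_matches_fast_kinetic(self, standard_design):
        """The instantaneous-hydrolysis idealisation tracks the fast
        first-order realisation closely on the cascade. The agreement is
        ~1.6% rather than exact because the small equilibrium constant of
        the lumped GDP-man synthesis (Keq3 = 0.032) lets even the ~µM
        steady-state pyrophosphate of the kinetic mode drive a noticeable
        reverse flux."""
        fast = simulate(build_model("cascade"), standard_design)
        strict = simulate(
            build_model("cascade", ppa_mode="strict_instant"), standard_design
        )
        scale = fast["GDPM"].max()
        diff = np.abs(strict["GDPM"] - fast["GDPM"]) / scale
        assert diff.max() < 2e-2
        assert np.all(strict["PP"] == 0.0)
        # strict mode converts any initial pyrophosphate charge up front
        charged = standard_cascade_design(
            initial_concentrations={"man": 6e-3, "ADP": 0.8e-3,
                                    "GDP": 0.8e-3, "PP": 1e-4,
                                    "PolyP": 56e-3},
        )
        res = simulate(build_model("cascade", ppa_mode="strict_instant"),
                       charged)
        assert res["Pi"][0] == pytest.approx(2e-4)

    def test_solver_report_fields(self, cascade_result):
        report = cascade_result.solver_report
        assert report["rtol"] == 1e-8
        assert report["nfev"] > 0
        assert set(report["conservation_drift"]) == {
            "adenine", "guanine", "mannose", "lipid"
        }
        assert report["polyp_pool_nonnegative"]

    def test_design_validation(self):
        with pytest.raises(ValidationError):
            ExperimentDesign({"man": 1e-3}, {}, sample_times=(0.0, 5.0, 5.0))
        with pytest.raises(ValidationError):
            ExperimentDesign({"man": 1e-3}, {}, t_end=10.0,
                             sample_times=(0.0, 20.0))
        with pytest.raises(ValidationError):
            ExperimentDesign({"man": -1e-3}, {})
        with pytest.raises(ValidationError):
            ExperimentDesign({"man": 1e-3}, {"glk": -0.5})


def _linear_result(slope_M_per_min=1e-6, n=25, constant=False):
    """Fabricated trajectory for observable arithmetic tests."""
    model = build_model("cascade")
    times = np.linspace(0.0, 240.0, n)
    conc = np.zeros((model.n_species, n))
    series = (np.full(n, 5e-4) if constant
              else 1e-5 + slope_M_per_min * times)
    conc[model.species_index("GDPM")] = series
    design = ExperimentDesign({"man": 1e-3}, {}, t_end=240.0)
    return SimulationResult(model, design, times, conc,
                            np.zeros((7, n)), {})


class TestObservables:
    def test_yield_arithmetic(self):
        result = _linear_result()
        result.concentrations[result.model.species_index("GDPM"), -1] = 5.66e-4
        assert yield_vs_reference(result, "GDPM", 8e-4) == pytest.approx(70.75)

    def test_yield_edge_cases(self):
        result = _linear_result()
        i = result.model.species_index("GDPM")
        result.concentrations[i, -1] = 0.0
        assert yield_vs_reference(result, "GDPM", 8e-4) == 0.0
        result.concentrations[i, -1] = 8e-4
        assert yield_vs_reference(result, "GDPM", 8e-4) == pytest.approx(100.0)
        with pytest.raises(ValidationError):
            yield_vs_reference(result, "GDPM", 0.0)

    def test_steady_rate_on_exact_line(self):
        slope, lag = steady_rate(_linear_result(1e-6), "GDPM")
        assert slope == pytest.approx(1.0)
        assert lag == 0.0

    def test_steady_rate_on_constant_series(self):
        slope, _ = steady_rate(_linear_result(constant=True), "GDPM")
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_steady_rate_needs_three_points(self):
        result = _linear_result(n=25)
        with pytest.raises(ValidationError):
            steady_rate(result, "GDPM", window=(239.0, 240.0))

    def test_cascade_lag_phase_detected(self, cascade_result):
        """The cascade shows a lag of tens of minutes before settling into
        its steady production phase."""
        slope, lag = steady_rate(cascade_result, "GDPM")
        assert slope > 0
        assert 30.0 <= lag <= 150.0

    def test_time_to_fraction_interpolates(self):
        result = _linear_result()
        i = result.model.species_index("Phyt")
        result.concentrations[i] = np.linspace(1e-3, 0.0, result.times.size)
        assert time_to_fraction(result, "Phyt", 0.5) == pytest.approx(120.0)
        assert time_to_fraction(result, "Phyt", 0.0) == 0.0

    def test_time_to_fraction_sentinel_and_errors(self):
        result = _linear_result(constant=True)
        i = result.model.species_index("Phyt")
        result.concentrations[i] = 1e-3  # never converted
        assert time_to_fraction(result, "Phyt", 0.99) == np.inf
        result.concentrations[i] = 0.0
        with pytest.raises(ValidationError):
            time_to_fraction(result, "Phyt", 0.5)
        with pytest.raises(ValidationError):
            time_to_fraction(result, "GDPM", 1.5)

    def test_alg1_bulk_conversion_is_fast(self):
        """The squared-law mannosyl transfer converts the bulk (90%) of the
        acceptor within ~20 min at 0.1 g/L enzyme."""
        design = ExperimentDesign(
            {"GDPM": 1.5e-3, "Phyt": 0.7e-3}, {"alg1": 0.1}, t_end=60.0
        )
        result = simulate(build_model("alg1_only"), design)
        assert time_to_fraction(result, "Phyt", 0.9) < 20.0
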