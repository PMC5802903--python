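"""Closed-form vertex enumeration, optimum selection and regime labels."""

import math

import pytest
from hypothesis import given

from warburglp import (
    ModelSpec,
    UNLIMITED,
    classify_regime,
    enumerate_vertices,
    fermentation_favored,
    restore_v1,
    solve,
    substrate_thresholds,
)
from warburglp.model_core import DegenerateCostError, DegenerateYieldError

from strategies import model_specs


def _by_label(vertices):
    return {v.label: v for v in vertices}


class TestEnumerateVertices:
    def test_unlimited_yields_four_vertices(self, low_cost_spec):
        labels = [v.label for v in enumerate_vertices(low_cost_spec)]
        assert labels == ["O", "A", "B", "C"]

    def test_capped_mix_vertex_matches_printed_fluxes(self):
        spec = ModelSpec.from_values(alpha3=50.0, V1=25.0)
        a2 = _by_label(enumerate_vertices(spec))["A2"]
        assert a2.flux.v1 == pytest.approx(25.0)
        assert a2.flux.v2 == pytest.approx(21.94, abs=0.005)
        assert a2.flux.v3 == pytest.approx(3.06, abs=0.005)
        assert a2.feasible

    def test_reverse_mix_vertex_matches_printed_fluxes(self):
        spec = ModelSpec.from_values(alpha3=50.0, V1=2.0)
        a4 = _by_label(enumerate_vertices(spec))["A4"]
        assert a4.flux.v2 == pytest.approx(-1.92, abs=0.005)
        assert a4.flux.v3 == pytest.approx(3.92, abs=0.005)
        assert a4.feasible

    def test_table_closed_form_identities(self):
        # phi(A) = m1*G/(a1+a2); phi(B) = (m1+m3)*G/(a1+a3); phi(C) = m3*G/(a2rev+a3)
        spec = ModelSpec.from_values(
            m1=3.0, m3=17.0, alpha1=0.7, alpha2=1.3, alpha2_rev=0.4,
            alpha3=9.0, Gamma=123.0,
        )
        vs = _by_label(enumerate_vertices(spec))
        assert vs["A"].atp == pytest.approx(3.0 * 123.0 / 2.0, rel=1e-12)
        assert vs["B"].atp == pytest.approx(20.0 * 123.0 / 9.7, rel=1e-12)
        assert vs["C"].atp == pytest.approx(17.0 * 123.0 / 9.4, rel=1e-12)

    def test_zero_budget_collapses_everything_to_origin(self):
        spec = ModelSpec.from_values(Gamma=0.0, V1=0.0)
        for v in enumerate_vertices(spec):
            assert v.flux.as_tuple() == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)
            assert v.atp == 0.0

    def test_equal_fermentation_and_respiration_cost_is_degenerate(self):
        spec = ModelSpec.from_values(alpha2=10.0, alpha3=10.0 + 1e-12, V1=5.0)
        with pytest.raises(DegenerateCostError, match="alpha"):
            enumerate_vertices(spec)

    def test_irreversible_excludes_reverse_vertices(self):
        spec = ModelSpec.from_values(alpha3=50.0, V1=2.0, fermentation_reversible=False)
        vs = _by_label(enumerate_vertices(spec))
        assert not vs["C"].feasible
        assert not vs["A4"].feasible

    def test_binding_constraints_hold_with_equality(self):
        spec = ModelSpec.from_values(alpha3=50.0, V1=25.0)
        c = spec.costs
        for v in enumerate_vertices(spec):
            if "c" in v.binding:
                load = (c.alpha1 + c.alpha2) * v.flux.v2 + (c.alpha1 + c.alpha3) * v.flux.v3
                assert load == pytest.approx(c.Gamma, rel=1e-9)
            if "g" in v.binding:
                assert v.flux.v1 == pytest.approx(25.0, rel=1e-9)

    def test_unbounded_pure_fermentation_raises(self):
        spec = ModelSpec.from_values(alpha1=0.0, alpha2=0.0, alpha3=5.0)
        with pytest.raises(DegenerateCostError, match="unbounded"):
            enumerate_vertices(spec)


class TestSolve:
    def test_cheap_respiration_selects_pure_respiration(self, low_cost_spec):
        sol = solve(low_cost_spec)
        assert [v.label for v in sol.optima] == ["B"]
        assert sol.regime == "pure_respiration"
        assert sol.phi_star == pytest.approx(581.8, abs=0.05)
        assert sol.optima[0].yield_ratio == pytest.approx(32.0)

    def test_costly_respiration_selects_pure_fermentation(self, high_cost_spec):
        sol = solve(high_cost_spec)
        assert [v.label for v in sol.optima] == ["A"]
        assert sol.regime == "pure_fermentation"
        assert sol.phi_star == pytest.approx(200.0)
        assert sol.optima[0].yield_ratio == pytest.approx(2.0)

    def test_tight_cap_with_costly_respiration(self):
        sol = solve(ModelSpec.from_values(alpha3=50.0, V1=3.92))
        assert sol.phi_star == pytest.approx(125.5, abs=0.05)

    def test_crossover_reports_degenerate_tie(self):
        sol = solve(ModelSpec.from_values(alpha3=31.0))
        assert {v.label for v in sol.optima} == {"A", "B"}
        assert sol.regime == "degenerate_tie"
        assert sol.phi_star == pytest.approx(200.0)

    @given(model_specs())
    def test_irreversibility_never_helps(self, spec):
        phi_rev = solve(spec.with_reversibility(True)).phi_star
        phi_irr = solve(spec.with_reversibility(False)).phi_star
        assert phi_irr <= phi_rev + 1e-9 * max(1.0, phi_rev)

    @given(model_specs())
    def test_homogeneity_in_budget_and_cap(self, spec):
        lam = 3.5
        c = spec.costs
        scaled = ModelSpec.from_values(
            alpha1=c.alpha1, alpha2=c.alpha2, alpha2_rev=c.alpha2_rev,
            alpha3=c.alpha3, Gamma=lam * c.Gamma,
            V1=spec.limit.V1 if spec.limit.is_unlimited else lam * spec.limit.V1,
            fermentation_reversible=spec.fermentation_reversible,
        )
        a, b = solve(spec), solve(scaled)
        assert b.phi_star == pytest.approx(lam * a.phi_star, rel=1e-9, abs=1e-9)

    @given(model_specs())
    def test_optima_are_feasible_and_tied(self, spec):
        sol = solve(spec)
        assert sol.phi_star >= 0.0
        for v in sol.optima:
            assert v.feasible
            assert v.atp == pytest.approx(sol.phi_star, rel=1e-9, abs=1e-9)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "reduced, regime",
        [
            ((100.0, 0.0), "pure_fermentation"),
            ((0.0, 0.0), "quiescent"),
            ((-14.26, 18.18), "respiration_with_reverse_fermentation"),
            ((0.0, 18.18), "pure_respiration"),
            ((21.94, 3.06), "respiro_fermentation"),
        ],
    )
    def test_labels(self, reduced, regime):
        assert classify_regime(restore_v1(*reduced)) == regime


class TestCrossoverAndThresholds:
    def test_costly_respiration_favors_fermentation(self, high_cost_spec):
        cmp = fermentation_favored(high_cost_spec)
        assert cmp.favored
        assert cmp.yield_ratio == pytest.approx(0.0625)
        assert cmp.cost_ratio == pytest.approx(2.0 / 51.0)

    def test_cheap_respiration_favors_respiration(self, low_cost_spec):
        cmp = fermentation_favored(low_cost_spec)
        assert not cmp.favored
        assert cmp.cost_ratio == pytest.approx(2.0 / 11.0)

    def test_crossover_flagged_at_equal_ratios(self):
        cmp = fermentation_favored(ModelSpec.from_values(alpha3=31.0))
        assert cmp.at_crossover
        assert not cmp.favored

    def test_zero_total_yield_raises(self, low_cost_spec):
        import dataclasses
        from warburglp import YieldCoefficients

        spec = dataclasses.replace(low_cost_spec, yields=YieldCoefficients(0.0, 0.0))
        with pytest.raises(DegenerateYieldError):
            fermentation_favored(spec)

    @pytest.mark.parametrize(
        "alpha3, expected",
        [(50.0, (3.92, 100.0)), (10.0, (18.18, 100.0))],
    )
    def test_threshold_values(self, alpha3, expected):
        spec = ModelSpec.from_values(alpha3=alpha3)
        v_low, v_high = substrate_thresholds(spec)
        assert v_low == pytest.approx(expected[0], abs=0.005)
        assert v_high == pytest.approx(expected[1])
        assert v_low < v_high

    def test_zero_budget_thresholds(self):
        spec = ModelSpec.from_values(Gamma=0.0)
        assert substrate_thresholds(spec) == (0.0, 0.0)
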