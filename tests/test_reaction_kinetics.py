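"""Tests for the kinetic schemes, their reduction, and the mass-action oracle."""

import dataclasses

import numpy as np
import pytest
import sympy

from fatecircuit import (
    FullNetworkParams,
    Model2Params,
    effective_activation_rate,
    full_network_rhs,
    integrate_full_network,
    reduce_model1,
    reduce_model2,
    rhs,
    steady_states,
)
from fatecircuit.reaction_kinetics import (
    SPECIES,
    equilibrated_state,
    full_network_steady_state,
    make_initial_state,
    reduced_rate_model2,
    symbolic_denominator,
    to_sbml,
)


def quasi_equilibrium_rate_oracle(m, X, Y):
    """Independent oracle for the reduced Model 1 rate: solve the
    promoter-occupancy equilibrium numerically at fixed (X, Y) and evaluate
    production minus degradation for protein X."""

    # unknowns: free, self-bound, cross-bound, doubly-bound promoter; the
    # binding balances at fixed protein levels are linear, so solve exactly
    A = np.array(
        [
            [m.K_x * X, -1.0, 0.0, 0.0],     # self-binding balance
            [m.K_yx * Y, 0.0, -1.0, 0.0],    # cross-binding balance
            [0.0, m.K_yx * Y, 0.0, -1.0],    # repressor on occupied promoter
            [1.0, 1.0, 1.0, 1.0],            # promoter conservation
        ]
    )
    z = np.linalg.solve(A, [0.0, 0.0, 0.0, m.x_tot])
    xX = z[1]
    return m.alpha_x * xX - m.delta_x * X


class TestEffectiveActivation:
    @pytest.mark.parametrize(
        "conc,expected", [(0.0, 0.0), (1.0, 0.5), (1e9, 1.0)]
    )
    def test_saturating_form(self, conc, expected):
        assert effective_activation_rate(1.0, 1.0, conc) == pytest.approx(expected, abs=1e-8)

    def test_monotone_and_bounded(self):
        vals = [effective_activation_rate(2.0, 3.0, c) for c in np.linspace(0, 50, 200)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert max(vals) < 3.0

    @pytest.mark.parametrize("K,alpha,conc", [(0.0, 1.0, 1.0), (1.0, -1.0, 1.0), (1.0, 1.0, -0.1)])
    def test_domain_errors(self, K, alpha, conc):
        with pytest.raises(ValueError):
            effective_activation_rate(K, alpha, conc)


class TestReduceModel1:
    def test_reference_mapping(self, model1_reference):
        g = reduce_model1(model1_reference)
        assert (g.a, g.f, g.b, g.c, g.d) == (1.0, 1.0, 1.0, 1.0, 0.5)

    def test_composite_parameter_mapping(self, model1_reference):
        m = dataclasses.replace(
            model1_reference, alpha_x=1.0, x_tot=1.0, K_x=0.5, K_yx=0.25, delta_x=0.5
        )
        g = reduce_model1(m)
        assert (g.a, g.bx, g.cx, g.dx) == (0.5, 0.5, 0.25, 0.5)

    def test_rate_vanishes_without_protein(self, model1_reference):
        g = reduce_model1(model1_reference)
        assert rhs((0.0, 3.0), g)[0] == 0.0

    @pytest.mark.parametrize("X,Y", [(0.0, 0.0), (0.3, 1.7), (2.0, 0.5), (4.0, 4.0)])
    def test_matches_numeric_quasi_equilibrium_oracle(self, model1_reference, X, Y):
        g = reduce_model1(model1_reference)
        assert rhs((X, Y), g)[0] == pytest.approx(
            quasi_equilibrium_rate_oracle(model1_reference, X, Y), abs=1e-9
        )


class TestReduceModel2:
    def test_factorizing_case_equals_model1(self, model1_reference, model2_factorizing):
        red = reduce_model2(model2_factorizing)
        assert red.factorizes
        assert red.generic == reduce_model1(model1_reference)
        # pointwise agreement of the two reduced rate functions
        g = reduce_model1(model1_reference)
        for X in np.linspace(0.0, 5.0, 20):
            for Y in np.linspace(0.0, 5.0, 20):
                m2 = reduced_rate_model2(model2_factorizing, X, Y)
                m1 = rhs((X, Y), g)
                assert abs(m1[0] - m2[0]) < 1e-12
                assert abs(m1[1] - m2[1]) < 1e-12

    def test_cooperative_case_does_not_factorize(self, model2_factorizing):
        m = dataclasses.replace(model2_factorizing, K_xxy=2.0)
        red = reduce_model2(m)
        assert not red.factorizes
        assert red.generic is None
        assert red.denom_x.XY == pytest.approx(2.0)  # K_x * K_xxy = 1 * 2

    def test_near_miss_reported_not_factorized(self, model2_factorizing):
        m = dataclasses.replace(model2_factorizing, K_xxy=model2_factorizing.K_yx * (1 + 1e-9))
        assert not reduce_model2(m).factorizes

    def test_cross_terms_vanish_without_repressor(self, model2_factorizing):
        m = dataclasses.replace(model2_factorizing, K_xxy=3.0)
        for X in (0.0, 0.5, 2.0):
            dX, _ = reduced_rate_model2(m, X, 0.0)
            expected = (
                m.alpha_x * m.x_tot * m.K_x * X / (1.0 + m.K_x * X) - m.delta_x * X
            )
            assert dX == pytest.approx(expected, abs=1e-14)

    def test_symbolic_cross_term_coefficient(self, model1_reference):
        # the Model 1 denominator expands with [X][Y] coefficient K_x*K_yx
        poly = symbolic_denominator("model1", model1_reference)
        X, Y = poly.gens
        coeff = poly.coeff_monomial(X * Y)
        assert coeff != 0
        assert float(coeff) == pytest.approx(
            model1_reference.K_x * model1_reference.K_yx, abs=1e-15
        )


class TestFullNetwork:
    def test_no_production_no_degradation_at_empty_state(self, model1_reference):
        p = FullNetworkParams(model1_reference)
        deriv = full_network_rhs(make_initial_state(p), p)
        assert np.allclose(deriv, 0.0)

    def test_promoter_conservation_in_rhs(self, model2_factorizing):
        p = FullNetworkParams(model2_factorizing, rate_scale=10.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = rng.uniform(0.0, 1.0, size=len(SPECIES))
            deriv = full_network_rhs(state, p)
            assert abs(deriv[0:4].sum()) < 1e-12  # x-locus species
            assert abs(deriv[4:8].sum()) < 1e-12  # y-locus species

    def test_negative_state_rejected(self, model1_reference):
        p = FullNetworkParams(model1_reference)
        state = make_initial_state(p)
        state[-1] = -0.1
        with pytest.raises(ValueError):
            full_network_rhs(state, p)

    def test_conservation_along_trajectory(self, model1_reference):
        p = FullNetworkParams(model1_reference, rate_scale=100.0)
        sol = integrate_full_network(p, make_initial_state(p, X=1.0, Y=0.2), t_end=50.0)
        totals_x = sol.y[0:4].sum(axis=0)
        totals_y = sol.y[4:8].sum(axis=0)
        assert np.max(np.abs(totals_x - model1_reference.x_tot)) <= 1e-9 * model1_reference.x_tot
        assert np.max(np.abs(totals_y - model1_reference.y_tot)) <= 1e-9 * model1_reference.y_tot

    def test_zero_protein_state_is_invariant(self, model1_reference):
        p = FullNetworkParams(model1_reference, rate_scale=10.0)
        sol = integrate_full_network(p, make_initial_state(p), t_end=20.0)
        assert np.max(np.abs(sol.y[8:10])) < 1e-12

    def test_steady_state_matches_reduced_model(self, model1_reference):
        # free-protein coordinates of the full network agree with the reduced
        # system's committed state within 1e-2 relative at large rate_scale
        g = reduce_model1(model1_reference)
        target = steady_states(g.with_q(2.0)).by_label("asym_x")
        m = dataclasses.replace(model1_reference, K_yx=2.0, K_xy=2.0)  # q = 2
        p = FullNetworkParams(m, rate_scale=1e3)
        st = full_network_steady_state(p, initial=make_initial_state(p, X=1.5, Y=0.0))
        assert abs(st[8] - target.x) / target.x < 1e-2

    def test_transient_converges_with_rate_scale(self, model1_reference):
        # the rapid-equilibrium reduction describes the *dynamics* only in the
        # fast-binding limit: at fixed finite time the discrepancy between the
        # full network's free proteins and the reduced trajectory shrinks
        # monotonically through rate_scale in {1, 1e2, 1e3}.  (Fixed points
        # themselves coincide at any rate_scale, since every binding flux
        # vanishes individually at steady state.)
        from scipy.integrate import solve_ivp

        g = reduce_model1(model1_reference)
        x0, y0, t_end = 0.6, 0.05, 6.0
        red = solve_ivp(
            lambda t, s: rhs((max(s[0], 0.0), max(s[1], 0.0)), g),
            (0, t_end), [x0, y0], rtol=1e-10, atol=1e-12,
        )
        ref = red.y[:, -1]
        errs = []
        for scale in (1.0, 1e2, 1e3):
            p = FullNetworkParams(model1_reference, rate_scale=scale)
            sol = integrate_full_network(p, equilibrated_state(p, x0, y0), t_end, n_out=2)
            errs.append(np.hypot(sol.y[8, -1] - ref[0], sol.y[9, -1] - ref[1]))
        assert errs[0] > errs[1] > errs[2]

    def test_pre_equilibrated_fixed_point_is_stationary(self, model1_reference):
        # start exactly on a reduced-model steady state with equilibrated
        # promoters: at large rate_scale the trajectory stays put
        m = dataclasses.replace(model1_reference, K_yx=2.0, K_xy=2.0)
        g = reduce_model1(m)
        s = steady_states(g).by_label("asym_x")
        p = FullNetworkParams(m, rate_scale=1e3)
        sol = integrate_full_network(p, equilibrated_state(p, s.x, s.y), t_end=50.0)
        assert abs(sol.y[8, -1] - s.x) < 1e-6


class TestSBMLExport:
    def test_document_structure(self, model2_factorizing):
        import xml.etree.ElementTree as ET

        doc = to_sbml(FullNetworkParams(model2_factorizing, rate_scale=100.0))
        root = ET.fromstring(doc)
        ns = "{http://www.sbml.org/sbml/level3/version2/core}"
        assert root.tag == f"{ns}sbml"
        species = root.findall(f".//{ns}species")
        assert {s.attrib["id"] for s in species} == set(SPECIES)
        assert len(root.findall(f".//{ns}reaction")) == 16
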