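"""Mass balances, homeostasis, growth velocity, and the Lagrangian update."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import fsolve

from airwaymorph import (ChallengeProtocol, ConstituentFields, GrownGeometry,
                         RateParams, SimulationConfig, advance_growth,
                         ecm_deposition_rate, growth_velocity, homeostatic_state,
                         mixture_dilatation, proliferation_rate, run_simulation,
                         source_terms, switching_rate)
from airwaymorph.growth import GridTanglingError, well_mixed_rhs


class TestRateModulation:
    def test_switching_tiers(self, rates):
        assert switching_rate(0.0, 0.0, rates) == rates.c_c0
        assert switching_rate(0.5 * (rates.mu_1 + rates.mu_2), 0.0, rates) == rates.c_c1
        assert switching_rate(rates.mu_2 + 1.0, 0.0, rates) == rates.c_c2

    def test_thresholds_are_strict(self, rates):
        # H(0) = 0: sitting exactly on a threshold stays in the lower tier
        assert switching_rate(rates.mu_1, 0.0, rates) == rates.c_c0
        assert ecm_deposition_rate(rates.mu_2, rates) == rates.c_e1

    def test_tension_mode_stress_term(self, rates):
        assert switching_rate(0.0, 2.0, rates) == pytest.approx(
            rates.c_c0 + 2.0 * rates.c_cp_f)
        assert switching_rate(0.0, -2.0, rates) == rates.c_c0

    def test_compression_mode_uses_magnitude(self):
        rates = RateParams(switch_mode="compression", prolif_mode="compression",
                          c_p_f=0.05)
        assert switching_rate(0.0, -1.0, rates) == pytest.approx(
            rates.c_c0 + rates.c_cp_f)
        assert switching_rate(0.0, 1.0, rates) == rates.c_c0
        assert proliferation_rate(-1.0, rates) == pytest.approx(rates.c_p0 + 0.05)

    def test_proliferation_tension_gate(self):
        rates = RateParams(c_p_f=0.05)
        assert proliferation_rate(0.0, rates) == rates.c_p0
        assert proliferation_rate(-3.0, rates) == rates.c_p0
        assert proliferation_rate(3.0, rates) == pytest.approx(rates.c_p0 + 0.15)

    def test_ecm_tiers(self, rates):
        assert ecm_deposition_rate(0.0, rates) == rates.c_e0
        assert ecm_deposition_rate(rates.mu_2 + 0.1, rates) == rates.c_e2


class TestSourceTerms:
    def test_random_fields_match_density_form_oracle(self):
        """Volume-fraction sources equal the density-form balances divided by
        the true density, for a non-unit rho_T (dual-implementation check)."""
        rates = RateParams(rho_T=2.5)
        rng = np.random.default_rng(42)
        phi_c, phi_p, phi_e = rng.uniform(0.01, 0.3, size=(3, 7))
        fields = ConstituentFields(phi_c=phi_c, phi_p=phi_p, phi_e=phi_e,
                                   phi_e_inner=np.full(4, 0.3))
        mu, tau = 0.9, rng.uniform(-2, 2, size=7)
        S_c, S_p, S_e, _ = source_terms(fields, mu, tau, rates)
        # independent evaluation in densities rho_a = Phi_a * rho_T
        rho = rates.rho_T
        c_cp = switching_rate(mu, tau, rates)
        s_c = rates.c_pc * phi_p * rho - rates.c_a * (phi_c * rho) ** 2 - c_cp * phi_c * rho
        s_p = (proliferation_rate(tau, rates) - rates.c_pc) * phi_p * rho + c_cp * phi_c * rho
        s_e = rates.c_pe * phi_p * rho + ecm_deposition_rate(mu, rates) - rates.c_de * phi_e * rho
        assert np.allclose(S_c, s_c / rho, rtol=0, atol=1e-12)
        assert np.allclose(S_p, s_p / rho, rtol=0, atol=1e-12)
        assert np.allclose(S_e, s_e / rho, rtol=0, atol=1e-12)

    def test_switching_seeds_proliferative_pool(self, rates):
        fields = ConstituentFields(phi_c=[0.2], phi_p=[0.0], phi_e=[0.1],
                                   phi_e_inner=[0.3])
        _, S_p, _, _ = source_terms(fields, rates.mu_2 + 1, 0.0, rates)
        assert S_p[0] > 0

    def test_inner_layer_inert_without_sbm_mode(self, rates):
        fields = ConstituentFields(phi_c=[0.2], phi_p=[0.02], phi_e=[0.08],
                                   phi_e_inner=[0.3])
        *_, S_e_inner = source_terms(fields, 5.0, 1.0, rates)
        assert np.all(S_e_inner == 0.0)

    def test_sbm_mode_quiescent_at_baseline_grows_with_inflammation(self, rates):
        fields = ConstituentFields(phi_c=[0.2], phi_p=[0.02], phi_e=[0.08],
                                   phi_e_inner=[0.3])
        *_, S0 = source_terms(fields, 0.0, 0.0, rates, sbm_thickening=True)
        *_, S2 = source_terms(fields, rates.mu_2 + 1, 0.0, rates, sbm_thickening=True)
        assert S0[0] == pytest.approx(0.0, abs=1e-15)
        assert S2[0] > 0


class TestHomeostaticState:
    def test_closed_form_annihilates_sources(self, rates):
        phi = homeostatic_state(rates)
        assert np.max(np.abs(well_mixed_rhs(phi, 0.0, 0.0, rates))) < 1e-12

    def test_symbolic_proliferative_fraction(self, rates):
        _, phi_p, _ = homeostatic_state(rates)
        expected = (rates.c_p0 * rates.c_c0**2
                    / (rates.c_a * (rates.c_pc - rates.c_p0) ** 2 * rates.rho_T))
        assert phi_p == pytest.approx(expected, rel=1e-14)

    def test_matches_independent_root_finder(self, rates):
        phi_star = np.array(homeostatic_state(rates))
        root = fsolve(lambda p: well_mixed_rhs(p, 0.0, 0.0, rates),
                      x0=np.array([0.1, 0.05, 0.1]), full_output=False)
        assert np.allclose(root, phi_star, rtol=1e-10)

    def test_fills_solid_fraction(self, rates):
        assert sum(homeostatic_state(rates)) == pytest.approx(0.30, abs=1e-12)

    def test_no_positive_steady_state_rejected(self, rates):
        with pytest.raises(ValueError):
            dataclasses.replace(rates, c_pc=0.4)  # c_pc <= c_p0

    def test_linear_stability(self, rates):
        """All eigenvalues of the well-mixed Jacobian at the steady state
        have negative real part (numerical differentiation)."""
        phi_star = np.array(homeostatic_state(rates))
        eps = 1e-7
        J = np.empty((3, 3))
        for j in range(3):
            dp = np.zeros(3)
            dp[j] = eps
            J[:, j] = (well_mixed_rhs(phi_star + dp, 0, 0, rates)
                       - well_mixed_rhs(phi_star - dp, 0, 0, rates)) / (2 * eps)
        assert np.all(np.linalg.eigvals(J).real < 0)


class TestMixtureGrowth:
    def test_dilatation_examples(self, rates):
        assert mixture_dilatation(0.0, 0.0, 0.0, rates) == 0.0
        assert mixture_dilatation(0.01, 0.01, 0.01, rates) == pytest.approx(0.1)

    def test_velocity_zero_for_zero_dilatation(self, geom):
        v_in, v_out = growth_velocity(0.0, 0.0, geom)
        assert np.all(v_in == 0.0) and np.all(v_out == 0.0)

    def test_velocity_constant_dilatation_closed_form(self, geom):
        """q = q0 in the outer layer only: v(xi_int) = -q0 (xi2^2 - xi_int^2)/(2 xi_int)."""
        q0 = 0.2
        v_in, v_out = growth_velocity(0.0, q0, geom)
        expected = -q0 * (geom.xi2**2 - geom.xi_int**2) / (2 * geom.xi_int)
        assert v_out[0] == pytest.approx(expected, rel=1e-12)
        assert v_in[-1] == pytest.approx(v_out[0], rel=1e-14)  # continuity
        assert v_out[-1] == 0.0  # pinned outer wall

    def test_positive_dilatation_grows_inward(self, geom):
        rng_q = np.abs(np.sin(geom.xi_outer_layer * 7)) * 0.1
        v_in, v_out = growth_velocity(0.0, rng_q, geom)
        assert np.all(v_in < 0)
        assert np.all(v_out[:-1] <= 0)


class TestAdvanceGrowth:
    def test_homeostatic_fixed_point(self, rates, geom):
        fields = ConstituentFields.homeostatic(rates, geom)
        phi0 = (fields.phi_c.copy(), fields.phi_p.copy(), fields.phi_e.copy())
        for _ in range(200):
            S = source_terms(fields, 0.0, 0.0, rates)
            q_out = mixture_dilatation(S[0], S[1], S[2], rates)
            q_in = S[3] / rates.phi_solid
            v_in, v_out = growth_velocity(q_in, q_out, geom)
            fields, geom = advance_growth(fields, geom, S, q_in, q_out,
                                          v_in, v_out, 0.05)
        assert np.max(np.abs(fields.phi_c - phi0[0])) < 1e-12
        assert abs(geom.xi1 - geom.R1) < 1e-12

    def test_solid_fraction_conserved_under_stimulation(self, rates, geom):
        fields = ConstituentFields.homeostatic(rates, geom)
        for _ in range(100):
            S = source_terms(fields, 2.0, 1.0, rates)  # severe tier + tension
            q_out = mixture_dilatation(S[0], S[1], S[2], rates)
            q_in = S[3] / rates.phi_solid
            v_in, v_out = growth_velocity(q_in, q_out, geom)
            fields, geom = advance_growth(fields, geom, S, q_in, q_out,
                                          v_in, v_out, 0.05)
        assert np.max(np.abs(fields.phi_solid_outer - 0.30)) < 1e-12
        assert geom.xi1 < geom.R1  # wall thickened inward
        assert geom.xi2 == geom.R2

    def test_grid_tangling_aborts(self, rates, geom):
        fields = ConstituentFields.homeostatic(rates, geom)
        S = source_terms(fields, 2.0, 1.0, rates)
        q_out = mixture_dilatation(S[0], S[1], S[2], rates)
        v_in, v_out = growth_velocity(0.0, q_out, geom)
        with pytest.raises(GridTanglingError):
            advance_growth(fields, geom, S, 0.0, q_out, v_in, v_out, dt=1e4)


def test_resolution_refinement_changes_little():
    """Halving dt and doubling the grid shifts the day-55 grown inner radius
    by < 0.5% in a challenged run."""
    proto = ChallengeProtocol.periodic(omega=0.2, horizon=56.0)
    vals = []
    for nodes, dt in ((51, 0.1), (101, 0.05)):
        cfg = SimulationConfig(protocol=proto, challenge_mode="inflammation_only",
                               nodes_per_layer=nodes, dt=dt)
        res = run_simulation(cfg)
        vals.append(float(np.interp(55.0, res.t, res.xi1)))
    assert abs(vals[1] - vals[0]) / vals[1] < 0.005
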