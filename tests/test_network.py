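"""Rate laws of the PLC/PKC/PA network: stated examples and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemopolarity.network import (
    MembraneState, CytosolState, plc_net_recruitment, pld_rate,
    pip2_hydrolysis_rate, lipid_interconversion, pkc_cycle_rates,
    marcks_cycle_rates, reaction_terms, pa_dag_ratio)
from chemopolarity.params import (RateParameters, FeedbackToggles,
                                  base_parameters, base_toggles,
                                  MEMBRANE_SPECIES, CYTOSOL_SPECIES)


def params_with(**kw) -> RateParameters:
    return base_parameters().replace(**kw)


class TestPLCRecruitment:
    def test_feedback_off_reduces_to_mass_action(self):
        p = params_with(K_PA=0.0, k_on_e=1.0, k_off_e=0.5)
        rate = plc_net_recruitment(10.0, 2.0, 0.3, 77.0, p)
        assert rate == pytest.approx(1.0 * (10 - 2) * 0.3 - 0.5 * 2)

    def test_epsilon_one_equals_kpa_zero(self):
        base = dict(r_local=10.0, e=3.0, E_surface=0.2, dp=55.0)
        p1 = params_with(K_PA=0.0, epsilon=0.3)
        p2 = params_with(K_PA=0.7, epsilon=1.0)
        assert plc_net_recruitment(**base, params=p1) == \
            pytest.approx(plc_net_recruitment(**base, params=p2))

    def test_pa_factor_at_unit_occupancy(self):
        # K_PA*dp = 1, eps = 0.1: off-rate factor (1 + 0.1)/2 = 0.55
        p = params_with(K_PA=0.1, epsilon=0.1, k_on_e=1.0, k_off_e=1.0)
        on_only = plc_net_recruitment(10.0, 0.0, 1.0, 10.0, p)
        assert on_only == pytest.approx(10.0)
        with_e = plc_net_recruitment(10.0, 1.0, 1.0, 10.0, p)
        assert on_only - with_e == pytest.approx(1.0 * 1.0 + 0.55 * 1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            plc_net_recruitment(-1.0, 0.0, 0.1, 0.0, base_parameters())
        with pytest.raises(ValueError):
            plc_net_recruitment(1.0, 2.0, 0.1, 0.0, base_parameters())

    @given(dp1=st.floats(0, 1e4), dp2=st.floats(0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_effective_off_rate_monotone_in_pa(self, dp1, dp2):
        """Off-rate is non-increasing in PA when epsilon < 1."""
        p = params_with(K_PA=0.01, epsilon=0.05)
        lo, hi = min(dp1, dp2), max(dp1, dp2)
        e = 1.0
        # net rate with zero on-term isolates the off-term
        off_lo = -plc_net_recruitment(e, e, 0.0, lo, p)
        off_hi = -plc_net_recruitment(e, e, 0.0, hi, p)
        assert off_hi <= off_lo + 1e-12


class TestPLDRate:
    def test_no_pkc_gives_basal(self):
        p = params_with(gamma=10.0, K_PLD=1.0)
        assert pld_rate(0.0, p) == pytest.approx(p.V_synth_dp)

    def test_gamma_one_is_flat(self):
        p = params_with(gamma=1.0, K_PLD=1.0)
        for c in (0.0, 1.0, 100.0):
            assert pld_rate(c, p) == pytest.approx(p.V_synth_dp)

    def test_half_saturation_value(self):
        # K_PLD*c* = 1, gamma = 10, n = 2 -> V*(1+10)/2 = 5.5 V
        p = params_with(gamma=10.0, K_PLD=0.5, n_hill=2)
        assert pld_rate(2.0, p) == pytest.approx(5.5 * p.V_synth_dp)

    @given(c=st.floats(0, 1e6))
    @settings(max_examples=60, deadline=None)
    def test_bounds(self, c):
        """V_synth_dp <= rate <= gamma * V_synth_dp for all c*."""
        p = params_with(gamma=8.0, K_PLD=0.37, n_hill=2)
        v = pld_rate(c, p)
        assert p.V_synth_dp * (1 - 1e-12) <= v <= \
            p.gamma * p.V_synth_dp * (1 + 1e-12)


class TestHydrolysisAndLipids:
    def test_bilinear_form(self):
        p = params_with(K_m_hyd=0.0)
        assert pip2_hydrolysis_rate(0.0, 500.0, p) == 0.0
        assert pip2_hydrolysis_rate(3.0, 0.0, p) == 0.0
        r1 = pip2_hydrolysis_rate(2.0, 300.0, p)
        assert pip2_hydrolysis_rate(4.0, 300.0, p) == pytest.approx(2 * r1)

    def test_saturable_variant(self):
        p = params_with(K_m_hyd=100.0)
        r = pip2_hydrolysis_rate(1.0, 100.0, p)
        assert r == pytest.approx(p.k_hyd * 100.0 / 2.0)

    def test_interconversion_linearity(self):
        p = base_parameters()
        assert lipid_interconversion(0.0, 0.0, p) == \
            (pytest.approx(0), pytest.approx(0), pytest.approx(0))
        f1, _, _ = lipid_interconversion(5.0, 0.0, p)
        f3, _, _ = lipid_interconversion(5.0, 0.0, p.scaled("k_DAGK", 3.0))
        assert f3 == pytest.approx(3 * f1)

    def test_pa_dag_steady_ratio(self):
        """Steady dp/d approaches k_DAGK/(k_PAP + k_basal_dp) when the PLD
        source is negligible (the lipid-interconversion balance line)."""
        from scipy.integrate import solve_ivp
        p = params_with(k_DAGK=0.2, k_PAP=0.075, k_basal_dp=0.025,
                        V_synth_dp=0.0)

        def odes(t, y):
            d, dp = y
            to_pa, to_dag, deg = lipid_interconversion(d, dp, p)
            return [1.0 - to_pa + to_dag, to_pa - to_dag - deg]

        sol = solve_ivp(odes, (0, 5000), [0.0, 0.0], rtol=1e-10, atol=1e-12)
        d, dp = sol.y[:, -1]
        assert dp / d == pytest.approx(pa_dag_ratio(p), rel=1e-6)
        assert pa_dag_ratio(p) == pytest.approx(0.2 / 0.1)


class TestPKCCycle:
    def test_all_zero_fluxes(self):
        fx = pkc_cycle_rates(0.0, 0.0, 0.0, 0.0, base_parameters())
        assert all(np.all(v == 0) for v in fx.values())

    def test_binding_equilibrium_without_cycling(self):
        """With the inactivation cycle off, steady c* is the binding
        equilibrium k_on_c d C / k_off_c."""
        from scipy.integrate import solve_ivp
        p = params_with(k_dp_c=0.0, k_rp_c=0.0, k_rel_c=0.0)
        d, C = 40.0, 0.3

        def ode(t, y):
            fx = pkc_cycle_rates(d, y[0], 0.0, C, p)
            return [fx["bind"] - fx["unbind"]]

        sol = solve_ivp(ode, (0, 2000), [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(p.k_on_c * d * C / p.k_off_c,
                                             rel=1e-6)

    def test_steady_cstar_decreases_with_off_rate(self):
        """Raising k_off_c 10/3-fold lowers steady c* accordingly."""
        from scipy.integrate import solve_ivp

        def steady_cstar(p):
            def ode(t, y):
                fx = pkc_cycle_rates(40.0, y[0], y[1], 0.3, p)
                return [fx["bind"] - fx["unbind"] - fx["deact"] + fx["react"],
                        fx["deact"] - fx["react"] - fx["release"]]
            sol = solve_ivp(ode, (0, 5000), [0.0, 0.0], rtol=1e-10,
                            atol=1e-12)
            return sol.y[0, -1]

        p = base_parameters()
        hi = steady_cstar(p)
        lo = steady_cstar(p.scaled("k_off_c", 10 / 3))
        assert lo < hi
        # with cycling rates small relative to k_off_c the scaling is
        # close to inverse-proportional
        assert hi / lo == pytest.approx(10 / 3, rel=0.25)


class TestMARCKSCycle:
    def test_no_pkc_no_phosphorylation(self):
        fx = marcks_cycle_rates(10.0, 50.0, 500.0, 0.0, 1.0,
                                base_parameters())
        assert fx["phos_free"] == 0 and fx["phos_bound"] == 0
        assert fx["capture"] > 0 and fx["release_p"] > 0

    def test_marcks_toggle_zeroes_everything(self):
        tog = FeedbackToggles(marcks=False)
        fx = marcks_cycle_rates(10.0, 50.0, 500.0, 5.0, 1.0,
                                base_parameters(), tog)
        assert all(np.all(v == 0) for v in fx.values())

    def test_phosphorylated_fraction_monotone_in_cstar(self):
        """The isolated cycle's steady phosphorylated fraction increases
        with active PKC (brute-force ODE steady states over a c* grid)."""
        from scipy.integrate import solve_ivp
        p = base_parameters()
        sv = 0.002

        def steady_fraction(cstar):
            def ode(t, y):
                m_free, m_pip2, M, M_p = y
                fx = marcks_cycle_rates(m_free, m_pip2, 500.0, cstar, M, p)
                return [fx["insert"] - fx["retrieve"] - fx["capture"]
                        + fx["release_p"] - fx["phos_free"],
                        fx["capture"] - fx["release_p"] - fx["phos_bound"],
                        (-fx["insert"] + fx["retrieve"]) * sv
                        + p.k_deph_M * M_p,
                        (fx["phos_free"] + fx["phos_bound"]) * sv
                        - p.k_deph_M * M_p]
            sol = solve_ivp(ode, (0, 50000), [0, 0, 10.0, 0.0],
                            rtol=1e-9, atol=1e-11, method="BDF")
            m_free, m_pip2, M, M_p = sol.y[:, -1]
            return M_p / (M + M_p)

        grid = [0.0, 1.0, 5.0, 20.0, 80.0]
        fracs = [steady_fraction(c) for c in grid]
        assert all(b > a - 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == pytest.approx(0.0, abs=1e-9)


class TestReactionTerms:
    def test_mismatched_mesh_raises(self):
        mem = MembraneState.zeros(5)
        cyt = CytosolState.uniform(4, 0.1, 0.5, 10.0, 0.0)
        with pytest.raises(ValueError):
            reaction_terms(mem, cyt, np.zeros(5), base_parameters(),
                           base_toggles())

    def test_pkc_copy_flux_balance_pointwise(self):
        """PKC gains on the membrane equal losses from the cytosol at every
        node (conservation by construction)."""
        rng = np.random.default_rng(7)
        n = 17
        mem = MembraneState(*[rng.uniform(0, 50, n) for _ in range(8)])
        mem.e = np.minimum(mem.e, 5.0)
        cyt = CytosolState(*[rng.uniform(0, 2, n) for _ in range(4)])
        r = np.full(n, 10.0)
        src, flux = reaction_terms(mem, cyt, r, base_parameters(),
                                   base_toggles())
        np.testing.assert_allclose(src["c_star"] + src["c_inact"],
                                   -flux["C"], rtol=1e-12)
        np.testing.assert_allclose(src["e"], -flux["E"], rtol=1e-12)

    def test_dag_backbone_closed_through_pkc_cycle(self):
        """Free DAG + PKC-bound DAG changes only through hydrolysis and the
        PA interconversion, not through PKC binding."""
        rng = np.random.default_rng(11)
        n = 9
        mem = MembraneState(*[rng.uniform(0, 50, n) for _ in range(8)])
        mem.e = np.minimum(mem.e, 5.0)
        cyt = CytosolState(*[rng.uniform(0, 2, n) for _ in range(4)])
        p = base_parameters()
        src, _ = reaction_terms(mem, cyt, np.full(n, 10.0), p,
                                base_toggles())
        d_tot_rate = src["d"] + src["c_star"] + src["c_inact"]
        hyd = pip2_hydrolysis_rate(mem.e, mem.p, p)
        to_pa, to_dag, _ = lipid_interconversion(mem.d, mem.dp, p)
        np.testing.assert_allclose(d_tot_rate, hyd - to_pa + to_dag,
                                   rtol=1e-12)
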