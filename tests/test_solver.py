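"""Implicit finite-volume solver: conservation, diffusion, oracle agreement."""

import numpy as np
import pytest

from chemopolarity.geometry import (StimulusSpec, build_cell_geometry,
                                    receptor_field)
from chemopolarity.network import MembraneState, CytosolState
from chemopolarity.params import (RateParameters, base_parameters,
                                  base_toggles, FeedbackToggles,
                                  MEMBRANE_SPECIES)
from chemopolarity.solver import (RDSolver, SimulationProtocol, run_protocol,
                                  well_mixed_oracle, basal_steady_state,
                                  initial_condition, compute_totals,
                                  N_MEM)


@pytest.fixture(scope="module")
def geom():
    # coarse test mesh: fast, resolves the minor axis with 4+ voxels
    return build_cell_geometry("symmetric", h=0.3, n_membrane=160)


def zero_rates(**overrides) -> RateParameters:
    """All reactions off; diffusion only."""
    base = base_parameters()
    zeroed = {k: 0.0 for k, v in base.to_dict().items()
              if not k.startswith("D_") and k != "n_hill"}
    zeroed["gamma"] = 1.0
    zeroed.update(overrides)
    return RateParameters(**{**base.to_dict(), **zeroed})


class TestDiffusionOnly:
    def test_copy_number_conservation_pure_diffusion(self, geom):
        """With all reactions off, every species' total is conserved to
        round-off by the conservative discretisation."""
        proto = SimulationProtocol(duration_phase1=50.0, reverse=False,
                                   max_dt=5.0, min_duration=1e9)
        solver = RDSolver(geom, zero_rates(), base_toggles(), proto)
        rng = np.random.default_rng(0)
        mem = MembraneState(*[rng.uniform(1, 2, geom.n_nodes)
                              for _ in range(8)])
        cyt = CytosolState(*[rng.uniform(0.1, 0.2, geom.n_voxels)
                             for _ in range(4)])
        y0 = solver.pack(mem, cyt)
        before = compute_totals(geom, mem, cyt)
        y1, _ = solver.integrate(y0, 50.0)
        after = compute_totals(geom, *solver.unpack(y1))
        for key in before:
            assert after[key] == pytest.approx(before[key], rel=1e-10)

    def test_membrane_point_spread_matches_heat_kernel(self, geom):
        """A point-like membrane bump spreads with variance 2 D t on the
        boundary loop (before wraparound)."""
        D = 1.0
        p = zero_rates(D_d=D)
        proto = SimulationProtocol(duration_phase1=8.0, reverse=False,
                                   max_dt=0.05, min_duration=1e9, rtol=1e-6)
        solver = RDSolver(geom, p, base_toggles(), proto)
        mem = MembraneState.zeros(geom.n_nodes)
        cyt = CytosolState.uniform(geom.n_voxels, 0, 0, 0, 0)
        i0 = 40   # away from the tips, where node spacing is regular
        mem.d[i0] = 1.0 / geom.ds[i0]
        y0 = solver.pack(mem, cyt)
        t_end = 8.0
        y1, _ = solver.integrate(y0, t_end)
        mem1, _ = solver.unpack(y1)
        # arclength coordinates relative to the bump
        s = np.concatenate([[0.0], np.cumsum(
            np.hypot(np.diff(geom.xs), np.diff(geom.ys)))])
        ds_rel = s - s[i0]
        w = mem1.d * geom.ds
        w = w / w.sum()
        var = float(np.sum(w * ds_rel ** 2))
        assert var == pytest.approx(2 * D * t_end, rel=0.05)

    def test_uniform_stimulus_preserves_mirror_symmetry(self, geom):
        """Uniform stimulus on the symmetric geometry never develops a
        front/back asymmetry (the scheme preserves the x -> -x mirror
        symmetry; membrane values may still vary with local
        surface-to-volume along the boundary)."""
        from chemopolarity.solver import _mirror_indices
        p = base_parameters()
        proto = SimulationProtocol(duration_phase1=30.0, reverse=False,
                                   max_dt=5.0, min_duration=1e9)
        solver = RDSolver(geom, p, base_toggles(), proto)
        solver.r_field = receptor_field(geom, StimulusSpec(0.05, 0.0))
        mem, cyt = initial_condition(geom, p, base_toggles())
        y1, _ = solver.integrate(solver.pack(mem, cyt), 30.0)
        mem1, cyt1 = solver.unpack(y1)
        mirror = _mirror_indices(geom)
        for s in MEMBRANE_SPECIES:
            a = getattr(mem1, s)
            asym = np.max(np.abs(a - a[mirror]))
            assert asym <= 1e-4 * (abs(a.mean()) + 1e-12) + 1e-9, s


class TestConservationWithReactions:
    def test_pool_conservation_over_stimulated_run(self, geom):
        """Whole-cell PLC, PKC and MARCKS copy numbers are constant to
        1e-5 relative over a stimulated 1,000 s simulation."""
        p = base_parameters()
        tog = base_toggles()
        proto = SimulationProtocol(duration_phase1=1000.0, reverse=False,
                                   max_dt=50.0, min_duration=1e9)
        solver = RDSolver(geom, p, tog, proto)
        solver.r_field = receptor_field(geom, StimulusSpec(0.1, 0.1))
        mem0, cyt0 = initial_condition(geom, p, tog)
        before = compute_totals(geom, mem0, cyt0)
        y1, _ = solver.integrate(solver.pack(mem0, cyt0), 1000.0)
        after = compute_totals(geom, *solver.unpack(y1))
        for key in ("PLC", "PKC", "MARCKS"):
            assert after[key] == pytest.approx(before[key], rel=1e-5)

    def test_non_negativity_without_clipping(self, geom):
        p = base_parameters()
        proto = SimulationProtocol(duration_phase1=500.0, reverse=False,
                                   max_dt=50.0, min_duration=1e9)
        solver = RDSolver(geom, p, base_toggles(), proto)
        solver.r_field = receptor_field(geom, StimulusSpec(0.2, 0.1))
        mem0, cyt0 = initial_condition(geom, p, base_toggles())
        mins = []

        def record(t, y):
            mins.append(y.min() / max(1.0, np.abs(y).max()))

        solver.integrate(solver.pack(mem0, cyt0), 500.0, record=record)
        assert min(mins) > -1e-9


class TestBasalState:
    def test_basal_is_fixed_point_of_wm_system(self):
        p = base_parameters()
        tog = base_toggles()
        t, series = well_mixed_oracle(p, tog, 0.0, 1000.0)
        for name, vals in series.items():
            ref = abs(vals[0]) + 1e-9
            assert abs(vals[-1] - vals[0]) / ref < 1e-6, name

    def test_basal_stationarity_of_pde(self, geom):
        """Broadcast basal state drifts by < 0.1% over 1,000 s at r = 0."""
        p = base_parameters()
        tog = base_toggles()
        proto = SimulationProtocol(duration_phase1=1000.0, reverse=False,
                                   max_dt=100.0, min_duration=1e9)
        solver = RDSolver(geom, p, tog, proto)
        solver.r_field = np.zeros(geom.n_nodes)
        mem0, cyt0 = initial_condition(geom, p, tog)
        y0 = solver.pack(mem0, cyt0)
        y1, _ = solver.integrate(y0, 1000.0)
        rel = np.abs(y1 - y0) / (np.abs(y0) + 1e-6 * np.abs(y0).max())
        assert float(rel.max()) < 1e-5

    def test_conservation_in_oracle(self):
        """PLC/PKC/MARCKS pool expressions constant along the oracle."""
        from chemopolarity.solver import _surface_to_volume
        p = base_parameters()
        tog = base_toggles()
        sv = _surface_to_volume(None)
        t, s = well_mixed_oracle(p, tog, 15.0, 2000.0)
        plc = s["E"] + sv * s["e"]
        pkc = s["C"] + sv * (s["c_star"] + s["c_inact"])
        mar = s["M"] + s["M_p"] + sv * (s["m_free"] + s["m_pip2"])
        for series in (plc, pkc, mar):
            assert np.ptp(series) / series[0] < 1e-6

    def test_oracle_pa_dag_ratio(self):
        """Steady dp/d equals k_DAGK/(k_PAP+k_basal_dp) when the PLD source
        is removed."""
        p = base_parameters().replace(V_synth_dp=0.0)
        tog = base_toggles()
        # basal state has d = dp = 0 without the PLD source; stimulate
        # mildly (strong stimulation oscillates and never settles)
        t, s = well_mixed_oracle(p, tog, 3.0, 100000.0)
        lam = p.k_DAGK / (p.k_PAP + p.k_basal_dp)
        assert s["dp"][-1] / s["d"][-1] == pytest.approx(lam, rel=1e-3)

    def test_oracle_rejects_negative_r(self):
        with pytest.raises(ValueError):
            well_mixed_oracle(base_parameters(), base_toggles(), -1.0, 10.0)


class TestToggleEquivalence:
    def test_kpa_zero_equals_epsilon_one(self):
        """PFL 1 off two ways: K_PA = 0 and epsilon = 1 give identical
        trajectories."""
        tog = base_toggles()
        p1 = base_parameters().replace(K_PA=0.0)
        p2 = base_parameters().replace(epsilon=1.0)
        t1, s1 = well_mixed_oracle(p1, tog, 13.0, 500.0)
        t2, s2 = well_mixed_oracle(p2, tog, 13.0, 500.0)
        for name in s1:
            np.testing.assert_allclose(s1[name], s2[name], rtol=1e-6,
                                       atol=1e-10)

    def test_kpld_zero_equals_gamma_one(self):
        """PFL 2 off two ways: K_PLD = 0 and gamma = 1."""
        tog = FeedbackToggles(pfl1=True, pfl2=True, marcks=True)
        p1 = base_parameters().replace(K_PLD=0.0, gamma=5.0)
        p2 = base_parameters().replace(K_PLD=0.2, gamma=1.0)
        t1, s1 = well_mixed_oracle(p1, tog, 13.0, 500.0)
        t2, s2 = well_mixed_oracle(p2, tog, 13.0, 500.0)
        for name in s1:
            np.testing.assert_allclose(s1[name], s2[name], rtol=1e-6,
                                       atol=1e-10)


class TestOracleEquivalence:
    def test_large_diffusivity_limit_matches_oracle(self):
        """With diffusivities scaled hugely, PDE probes match the
        well-mixed ODE solution within 1%."""
        geom = build_cell_geometry("symmetric", h=0.3, n_membrane=100)
        p = base_parameters()
        big = {k: 1e6 * v for k, v in p.to_dict().items()
               if k.startswith("D_")}
        p_big = p.replace(**big)
        tog = base_toggles()
        t_end = 2000.0
        proto = SimulationProtocol(duration_phase1=t_end, reverse=False,
                                   max_dt=20.0, min_duration=1e9, rtol=1e-6)
        r_scalar = 6.0
        solver = RDSolver(geom, p_big, tog, proto)
        solver.r_field = np.full(geom.n_nodes, r_scalar)
        mem0, cyt0 = initial_condition(geom, p_big, tog)
        y1, _ = solver.integrate(solver.pack(mem0, cyt0), t_end)
        mem1, cyt1 = solver.unpack(y1)
        t, s = well_mixed_oracle(p, tog, r_scalar, t_end, geometry=geom)
        for name in MEMBRANE_SPECIES:
            pde_val = float(getattr(mem1, name).mean())
            ode_val = float(s[name][-1])
            scale = max(abs(ode_val), 1e-4)
            assert abs(pde_val - ode_val) / scale < 0.01, name


class TestProtocolDriver:
    def test_flat_run_with_zero_stimulus(self, geom):
        p = base_parameters()
        proto = SimulationProtocol(duration_phase1=2000.0, reverse=False,
                                   max_dt=100.0)
        res = run_protocol(geom, p, base_toggles(),
                           StimulusSpec(rfrac=1e-12, rsteep=0.0), proto)
        ph = res.phase1
        assert ph.reached_steady and not ph.oscillatory
        v = ph.probes["c_star_front"]
        assert abs(v[-1] - v[0]) <= 1e-6 * (abs(v[0]) + 1e-12)

    def test_probe_assignment_follows_gradient_direction(self, geom):
        p = base_parameters()
        proto = SimulationProtocol(duration_phase1=200.0, reverse=False,
                                   max_dt=50.0, min_duration=1e9)
        right, left = geom.probe_indices()
        res_fwd = run_protocol(geom, p, base_toggles(),
                               StimulusSpec(0.1, 0.1, +1), proto)
        assert res_fwd.phase1.front_index == right
        res_rev = run_protocol(geom, p, base_toggles(),
                               StimulusSpec(0.1, 0.1, -1), proto)
        assert res_rev.phase1.front_index == left

    def test_envelope_ordering(self, geom):
        p = base_parameters()
        proto = SimulationProtocol(duration_phase1=500.0, reverse=False,
                                   max_dt=50.0)
        res = run_protocol(geom, p, base_toggles(),
                           StimulusSpec(0.1, 0.1), proto)
        for lo, hi in res.phase1.envelope.values():
            assert hi >= lo
        assert res.phase1.reached_steady != res.phase1.oscillatory
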