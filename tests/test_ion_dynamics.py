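"""Chloride dynamics: Nernst conversions, flux laws, protocol integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clsense import configs
from clsense.ion_dynamics import (
    BathSolution,
    CompartmentSpec,
    MembraneModel,
    ProtocolEvent,
    TransportParams,
    channel_flux,
    invert_nernst,
    kcc2_flux,
    membrane_potential,
    nernst_ecl,
    nkcc1_flux,
    resting_cl,
    simulate_cli,
    total_flux,
)

CELL = CompartmentSpec(name="cell", volume=1767.146, surface=706.858)


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_ecl(150.0, 150.0) == 0.0

    def test_one_decade_is_the_slope(self):
        assert nernst_ecl(150.0, 15.0) == pytest.approx(-59.16, abs=1e-12)

    def test_resting_neuron_reversal(self):
        # 5.7 mM against 150 mM outside sits at -84 mV
        assert nernst_ecl(150.0, 5.7) == pytest.approx(-84.0, abs=0.05)
        assert invert_nernst(-84.0, 150.0) == pytest.approx(5.70, abs=0.005)

    def test_invert_trivial_points(self):
        assert invert_nernst(0.0, 150.0) == 150.0
        assert invert_nernst(-59.16, 150.0) == pytest.approx(15.0, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(cl_i=st.floats(0.2, 200.0), cl_o=st.floats(50.0, 200.0))
    def test_roundtrip_identity(self, cl_i, cl_o):
        e = nernst_ecl(cl_o, cl_i)
        assert invert_nernst(e, cl_o) == pytest.approx(cl_i, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            nernst_ecl(150.0, 0.0)
        with pytest.raises(ValueError):
            invert_nernst(-10.0, -1.0)


class TestChannelFlux:
    def test_zero_at_reversal(self):
        assert channel_flux(1.0, 0.5, -84.0, -84.0, CELL) == 0.0

    def test_depolarized_membrane_carries_chloride_in(self):
        assert channel_flux(1.0, 0.5, -45.0, -84.0, CELL) > 0

    def test_hyperpolarized_membrane_carries_chloride_out(self):
        assert channel_flux(1.0, 0.5, -107.0, -84.0, CELL) < 0


class TestKcc2Flux:
    def test_zero_at_product_equality(self):
        # k_i*cl_i == k_o*cl_o exactly
        assert kcc2_flux(2.5, 140.0, 140.0, 2.5, u=1.0,
                         furosemide_factor=0.0, comp=CELL) == 0.0

    def test_efflux_when_intracellular_product_larger(self):
        f = kcc2_flux(2.5, 150.0, 140.0, 20.0, 1.0, 0.0, CELL)
        assert f < 0

    def test_reverse_mode_influx_under_high_bath_potassium(self):
        f = kcc2_flux(140.0, 150.0, 140.0, 7.0, 1.0, 0.0, CELL)
        assert f > 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(k_o=st.floats(1.0, 150.0), cl_i=st.floats(0.5, 120.0))
    def test_sign_matches_product_difference(self, k_o, cl_i):
        f = kcc2_flux(k_o, 150.0, 140.0, cl_i, 1.0, 0.0, CELL)
        assert np.sign(f) == np.sign(k_o * 150.0 - 140.0 * cl_i)

    def test_furosemide_scales_flux(self):
        f0 = kcc2_flux(140.0, 150.0, 140.0, 7.0, 1.0, 0.0, CELL)
        f1 = kcc2_flux(140.0, 150.0, 140.0, 7.0, 1.0, 1.0, CELL, block=0.85)
        assert f1 == pytest.approx(0.15 * f0, rel=1e-12)


class TestMembranePotential:
    def test_clamp_overrides(self):
        mm = MembraneModel(clamp=-80.0)
        assert membrane_potential(BathSolution(), mm) == -80.0

    def test_symmetric_potassium(self):
        mm = MembraneModel(vm_weight=0.5, v_offset=-10.0)
        sol = BathSolution(k_o=140.0)
        assert membrane_potential(sol, mm, k_i=140.0) == pytest.approx(-5.0)

    def test_resting_potential_in_reported_range(self):
        vm = membrane_potential(BathSolution(), MembraneModel())
        assert -78.0 < vm < -72.0

    def test_monotone_in_bath_potassium(self):
        mm = MembraneModel()
        vs = [membrane_potential(BathSolution(k_o=k), mm)
              for k in (2.5, 10.0, 25.0, 100.0, 140.0)]
        assert all(b > a for a, b in zip(vs, vs[1:]))


class TestSimulate:
    def test_no_fluxes_means_constant_chloride(self):
        res = simulate_cli(
            [ProtocolEvent(0.0, BathSolution())], TransportParams(), [CELL],
            dt=0.1, t_end=60.0, cl0=7.0,
        )
        assert np.all(res.cl == 7.0)

    def test_self_convergence_under_dt_halving(self):
        tp = configs.fig5_glycine_kcl_config().transport
        protocol = [
            ProtocolEvent(0.0, configs.SOLUTIONS["control"]),
            ProtocolEvent(60.0, configs.SOLUTIONS["glycine_100kcl"]),
            ProtocolEvent(120.0, configs.SOLUTIONS["control"]),
        ]
        a = simulate_cli(protocol, tp, [CELL], dt=0.1, t_end=300.0, cl0=8.0)
        b = simulate_cli(protocol, tp, [CELL], dt=0.05, t_end=300.0, cl0=8.0)
        common = a.t
        cl_b = np.interp(common, b.t, b.cl[0])
        assert np.max(np.abs(a.cl[0] - cl_b) / cl_b) < 0.005

    def test_unordered_events_rejected(self):
        protocol = [
            ProtocolEvent(0.0, BathSolution()),
            ProtocolEvent(50.0, BathSolution()),
            ProtocolEvent(10.0, BathSolution()),
        ]
        with pytest.raises(ValueError):
            simulate_cli(protocol, TransportParams(), [CELL], dt=0.1, t_end=60.0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_cli([ProtocolEvent(0.0, BathSolution())], TransportParams(),
                         [CELL], dt=0.0, t_end=10.0)

    def test_set_cl_event_imposes_concentration(self):
        protocol = [
            ProtocolEvent(0.0, BathSolution()),
            ProtocolEvent(30.0, None, set_cl=150.0),
        ]
        res = simulate_cli(protocol, TransportParams(), [CELL],
                           dt=0.1, t_end=60.0, cl0=5.0)
        assert res.cl_at(20.0) == 5.0
        assert res.cl_at(50.0) == 150.0

    def test_resting_cl_is_a_flux_fixed_point(self):
        cfg = configs.fig7_extrusion_config()
        sol = cfg.protocol[0].solution
        rest = resting_cl(sol, cfg.transport, cfg.comps[0])
        vm = membrane_potential(sol, cfg.membrane)
        assert abs(total_flux(rest, sol, vm, cfg.transport, cfg.comps[0])) < 1e-9

    def test_kcc2_config_rests_below_mock_config(self):
        sol = configs.SOLUTIONS["control_strychnine"]
        kcc2 = configs.fig7_extrusion_config().transport
        mock = TransportParams(k_leak=kcc2.k_leak, cl_leak=kcc2.cl_leak)
        assert resting_cl(sol, kcc2, CELL) < resting_cl(sol, mock, CELL)


class TestNkcc1:
    def test_disabled_by_default(self):
        assert nkcc1_flux(140, 2.5, 150, 140, 7, u=0.0, comp=CELL) == 0.0

    def test_bumetanide_suppresses_in_simulation(self):
        """Every bath solution carries 10 uM bumetanide; NKCC1 stays silent."""
        tp = TransportParams(u_nkcc1=0.5)
        sol = BathSolution()  # bumetanide=10 by default
        vm = membrane_potential(sol, MembraneModel())
        f_with = total_flux(7.0, sol, vm, tp, CELL)
        f_without = total_flux(7.0, sol, vm, TransportParams(), CELL)
        assert f_with == f_without

    def test_inward_gradient_drives_influx_when_unblocked(self):
        sol = BathSolution(bumetanide=0.0)
        f = nkcc1_flux(sol.na_o, sol.k_o, sol.cl_o, 140.0, 7.0, u=0.5, comp=CELL)
        assert f > 0
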