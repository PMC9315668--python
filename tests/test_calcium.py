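"""Compartmental Ca2+ fluxes, ER-AZ coupling and IP3 metabolism."""

import numpy as np
import pytest

from boutonsim import (CalciumState, compute_fluxes, coupling_flux,
                       calcium_rhs, ip3_rhs, load_parameters)
from boutonsim.calcium import plc_g_fixed_point, FluxSet


@pytest.fixture
def rest_state():
    return CalciumState(Ca_cyt=0.1, Ca_IPRn=0.1, Ca_AZ=0.05,
                        Ca_total=56.0, IP3=0.1, PLC=0.0, G=0.0)


class TestFluxes:
    def test_pmca_half_saturation(self, wt_params, rest_state):
        rest_state.Ca_cyt = wt_params.calcium.K_PMCA
        f = compute_fluxes(rest_state, 0.0, 0.0, wt_params)
        assert f.JPMCA == pytest.approx(3.195 / 2, rel=1e-12)

    def test_serca_half_saturation(self, wt_params, rest_state):
        rest_state.Ca_cyt = wt_params.calcium.K_SERCA
        f = compute_fluxes(rest_state, 0.0, 0.0, wt_params)
        assert f.JSERCA == pytest.approx(5.0, rel=1e-12)

    def test_membrane_influx_arithmetic(self, wt_params, rest_state):
        # Jin = 0.03115 + 0.2 * IP3 at IP3 = 0.1 uM
        f = compute_fluxes(rest_state, 0.0, 0.0, wt_params)
        assert f.Jin == pytest.approx(0.05115, rel=1e-12)

    def test_er_leak_vanishes_at_zero_gradient(self, wt_params, rest_state):
        # choose Ca_total so that Ca_ER equals Ca_cyt
        ca = wt_params.calcium
        rest_state.Ca_total = (rest_state.Ca_cyt / ca.delta2
                               + rest_state.Ca_cyt
                               - rest_state.Ca_IPRn / ca.delta1
                               + rest_state.Ca_AZ)
        f = compute_fluxes(rest_state, 0.0, 0.0, wt_params)
        assert f.JER_leak == pytest.approx(0.0, abs=1e-14)

    def test_negative_concentration_rejected(self, wt_params, rest_state):
        rest_state.Ca_cyt = -0.1
        with pytest.raises(ValueError):
            compute_fluxes(rest_state, 0.0, 0.0, wt_params)


class TestCouplingFlux:
    def test_zero_on_balance_surface(self, wt_params):
        cp = wt_params.coupling_params
        ca_iprn = 1.3
        ca_az = np.sqrt(cp.kbar) * ca_iprn
        assert coupling_flux(ca_az, ca_iprn, cp) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_sign_reversal_across_surface(self, wt_params):
        cp = wt_params.coupling_params
        assert coupling_flux(10.0, 0.1, cp) > 0     # AZ -> IP3R microdomain
        assert coupling_flux(0.1, 10.0, cp) < 0     # reverse transfer

    def test_pure_forward_transfer_when_kbar_zero(self, wt_params):
        import dataclasses
        cp = dataclasses.replace(wt_params.coupling_params, kbar=1e-300)
        assert coupling_flux(5.0, 100.0, cp) > 0

    def test_presets_differ(self):
        nc = load_parameters(coupling="NC").coupling_params
        hc = load_parameters(coupling="HC").coupling_params
        assert (coupling_flux(5.0, 1.0, nc)
                != pytest.approx(coupling_flux(5.0, 1.0, hc)))

    def test_printed_denominator_guarded_at_pole(self, wt_params):
        import dataclasses
        cp = dataclasses.replace(wt_params.coupling_params,
                                 printed_denominator=True)
        val = coupling_flux(cp.Kc, 1.0, cp)   # exactly at the printed pole
        assert np.isfinite(val)


class TestCalciumRHS:
    def test_all_zero_fluxes_give_zero_derivatives(self, wt_params,
                                                   rest_state):
        zero = FluxSet(*([0.0] * 9))
        assert calcium_rhs(rest_state, zero, wt_params) == (0, 0, 0, 0)

    def test_total_conserved_without_membrane_fluxes(self, wt_params,
                                                     rest_state):
        f = compute_fluxes(rest_state, 0.3, 0.0, wt_params)
        f.Jin = 0.0
        f.JPMCA = 0.0
        f.JVGCC = 0.0
        d = calcium_rhs(rest_state, f, wt_params)
        assert d[3] == 0.0

    def test_coupling_moves_but_does_not_create_calcium(self, wt_params,
                                                        rest_state):
        # with only the coupling flux active, the (1/delta1)-weighted
        # microdomain contribution cancels the AZ contribution exactly
        cp = wt_params.calcium
        only_coupling = FluxSet(0, 0, 0, 0, 0, 0, 0, 0,
                                coupling_flux(5.0, 1.0,
                                              wt_params.coupling_params))
        d = calcium_rhs(rest_state, only_coupling, wt_params)
        assert d[1] / cp.delta1 + d[2] == pytest.approx(0.0, abs=1e-12)


class TestIP3Metabolism:
    def test_no_abeta_baseline_production(self, wt_params, rest_state):
        # q = 0: VPLC reduces to V0 and the G-protein drive to delta only
        m = wt_params.ip3_metabolism
        plc, g = plc_g_fixed_point(m)
        rest_state.PLC, rest_state.G = plc, g
        dip3, dplc, dg = ip3_rhs(rest_state, 0.0, m)
        assert dplc == pytest.approx(0.0, abs=1e-15)
        assert dg == pytest.approx(0.0, abs=1e-15)

    def test_plc_half_saturation_in_calcium(self, wt_params, rest_state):
        m = wt_params.ip3_metabolism
        rest_state.Ca_cyt = m.K_PLC
        rest_state.PLC = 1.0
        tau = 1.0 / (m.k3k + m.k5p)
        dip3_full = ip3_rhs(rest_state, 0.0, m)[0]
        # JPLC at half saturation is V0/2 (PLC activity 1, no Abeta)
        eta = m.k3k / (m.k3k + m.k5p)
        c2 = m.K_PLC ** 2
        jdeg = (eta * c2 / (c2 + m.K_IP3k ** 2) + 1 - eta) * rest_state.IP3
        assert dip3_full == pytest.approx((m.V0 / 2 - jdeg) / tau, rel=1e-9)

    def test_plc_fixed_point_closed_form(self, wt_params):
        m = wt_params.ip3_metabolism
        plc, g = plc_g_fixed_point(m)
        # two-state balance: kf*G*(tot - PLC) = kb*PLC
        assert m.kf_PLC * g * (m.PLC_tot - plc) == pytest.approx(
            m.kb_PLC * plc, rel=1e-12)

    def test_ip3_turnover_time_is_slow(self, wt_params, ad_params):
        for ps in (wt_params, ad_params):
            m = ps.ip3_metabolism
            tau = 1.0 / (m.k3k + m.k5p)
            assert tau > 100.0   # ms; IP3 must act as a slow messenger
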