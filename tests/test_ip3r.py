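"""Four-state IP3R model: rates, stationary distribution, stochastic paths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boutonsim import (cluster_open_fraction, dwell_time_stats,
                       occupancy_factors, simulate_channel,
                       stationary_distribution, stationary_open_probability,
                       transition_rates)
from boutonsim.ip3r import STATE_O, STATE_R, ChannelTrajectory


class TestOccupancyFactors:
    def test_half_saturation_at_KOd(self, wt_params):
        p = wt_params.ip3r
        occ = occupancy_factors(p.KOd, p)
        assert occ.KO == pytest.approx(p.a1 / 2, rel=1e-12)

    def test_saturation_limits(self, wt_params):
        p = wt_params.ip3r
        occ = occupancy_factors(1e9, p)
        assert occ.KO == pytest.approx(p.a1, rel=1e-6)
        assert occ.KI == pytest.approx(p.a3, rel=1e-6)
        # the activation occupancy has a tiny Hill exponent (nA ~ 0.093),
        # so it approaches a2 only logarithmically slowly
        assert 0.85 * p.a2 < occ.KA < p.a2

    def test_hill_form_against_hand_arithmetic(self, wt_params):
        # independent evaluation of a1*10^nO/(10^nO + KOd^nO)
        p = wt_params.ip3r
        expected = 17.05043 * 10 ** 2.473407 / (10 ** 2.473407
                                                + 0.909078 ** 2.473407)
        assert occupancy_factors(10.0, p).KO == pytest.approx(expected,
                                                              rel=1e-2)

    @given(ip3=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_amplitudes(self, wt_params, ip3):
        occ = occupancy_factors(ip3, wt_params.ip3r)
        p = wt_params.ip3r
        tol = 1.0 + 1e-12
        assert 0 <= occ.KO <= p.a1 * tol
        assert 0 <= occ.KA <= p.a2 * tol
        assert 0 <= occ.KI <= p.a3 * tol

    def test_monotone_in_ip3(self, wt_params):
        grid = np.geomspace(0.01, 50, 40)
        ko = [occupancy_factors(q, wt_params.ip3r).KO for q in grid]
        assert np.all(np.diff(ko) >= -1e-15)

    def test_negative_ip3_rejected(self, wt_params):
        with pytest.raises(ValueError):
            occupancy_factors(-0.1, wt_params.ip3r)


class TestTransitionRates:
    def test_harmonic_sum_at_one_micromolar(self, wt_params):
        # kRA = 1/(1/j01 + 1/j12) at Ca = 1 uM
        r = transition_rates(1.0, 10.0, wt_params.ip3r)
        assert r.kRA == pytest.approx(156.4, rel=0.01)

    def test_zero_calcium_absorbs_in_R(self, wt_params):
        r = transition_rates(0.0, 10.0, wt_params.ip3r)
        assert all(v == 0.0 for v in r.as_array())

    @given(ca=st.floats(0.01, 50.0), ip3=st.floats(0.05, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_open_transition_identity(self, wt_params, ca, ip3):
        # kAO*KA = kOA*KO = j22 for any ligand combination
        p = wt_params.ip3r
        r = transition_rates(ca, ip3, p)
        occ = occupancy_factors(ip3, p)
        assert r.kAO * occ.KA == pytest.approx(p.j22, rel=1e-9)
        assert r.kOA * occ.KO == pytest.approx(p.j22, rel=1e-9)

    def test_all_rates_nonnegative(self, ad_params):
        for ca in (0.05, 0.5, 5.0):
            for ip3 in (0.1, 1.0, 10.0):
                assert (transition_rates(ca, ip3, ad_params.ip3r)
                        .as_array() >= 0).all()


class TestStationaryDistribution:
    def test_probability_vector_on_ligand_grid(self, wt_params, ad_params):
        for p in (wt_params.ip3r, ad_params.ip3r):
            for ca in np.geomspace(0.05, 2.0, 6):
                for ip3 in np.geomspace(0.1, 10.0, 6):
                    pi = stationary_distribution(ca, ip3, p)
                    assert pi.shape == (4,)
                    assert (pi >= 0).all()
                    assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_detailed_balance_closed_form(self, wt_params):
        # pi is proportional to (1, KA c^2, KO c^2, KI c^5)
        p = wt_params.ip3r
        ca, ip3 = 0.7, 2.0
        occ = occupancy_factors(ip3, p)
        w = np.array([1.0, occ.KA * ca**2, occ.KO * ca**2, occ.KI * ca**5])
        pi = stationary_distribution(ca, ip3, p)
        assert pi == pytest.approx(w / w.sum(), rel=1e-8)

    def test_ad_above_wt_over_ligand_grid(self, wt_params, ad_params):
        for ca in np.geomspace(0.05, 2.0, 8):
            for ip3 in np.geomspace(0.1, 10.0, 8):
                po_wt = stationary_open_probability(ca, ip3, wt_params.ip3r)
                po_ad = stationary_open_probability(ca, ip3, ad_params.ip3r)
                assert po_ad >= po_wt - 1e-12

    def test_po_increases_with_ip3(self, wt_params):
        # dose-response trend: more IP3 opens the channel.  The increase is
        # not strictly monotone at the high end (the slowly saturating KA
        # occupancy keeps growing after KO has saturated, shaving ~0.3% off
        # the top of the curve), so small reversals are tolerated.
        for ca in (0.1, 0.25, 1.0):
            po = np.array([stationary_open_probability(ca, q,
                                                       wt_params.ip3r)
                           for q in np.geomspace(0.1, 10, 25)])
            assert po[-1] > 2 * po[0]
            assert np.all(np.diff(po) >= -0.01 * po.max())

    def test_degenerate_ligands_raise(self, wt_params):
        with pytest.raises(ValueError):
            stationary_open_probability(0.0, 10.0, wt_params.ip3r)


class TestSimulateChannel:
    def test_seed_reproducibility(self, wt_params):
        a = simulate_channel(0.5, 1.0, 0.001, 50.0, 7, wt_params.ip3r)
        b = simulate_channel(0.5, 1.0, 0.001, 50.0, 7, wt_params.ip3r)
        assert np.array_equal(a.states, b.states)

    def test_zero_calcium_never_leaves_rest(self, wt_params):
        traj = simulate_channel(0.0, 10.0, 0.001, 20.0, 3, wt_params.ip3r)
        assert (traj.states == STATE_R).all()

    def test_empirical_matches_stationary(self, wt_params):
        ca, ip3 = 1.0, 10.0
        traj = simulate_channel(ca, ip3, 0.0005, 20000.0, 11,
                                wt_params.ip3r)
        po = stationary_open_probability(ca, ip3, wt_params.ip3r)
        emp = float((traj.states == STATE_O).mean())
        # binomial-ish bound with an effective number of sojourns
        assert emp == pytest.approx(po, abs=0.02)

    def test_overflowing_dt_rejected(self, wt_params):
        with pytest.raises(ValueError, match="dt"):
            simulate_channel(20.0, 10.0, 0.01, 10.0, 0, wt_params.ip3r)


class TestDwellTimes:
    def test_open_time_approaches_closed_form(self, wt_params):
        ca, ip3 = 1.0, 10.0
        r = transition_rates(ca, ip3, wt_params.ip3r)
        expected = 1.0 / (r.kOA + r.kOI)
        traj = simulate_channel(ca, ip3, 0.0005, 20000.0, 5,
                                wt_params.ip3r)
        st_ = dwell_time_stats(traj)
        assert st_.tau_open == pytest.approx(expected, rel=0.15)

    def test_all_open_trajectory(self):
        traj = ChannelTrajectory(times=np.arange(5.0),
                                 states=np.full(5, STATE_O, dtype=np.int8),
                                 dt=1.0)
        assert dwell_time_stats(traj).p_open_empirical == 1.0

    def test_no_openings_raises(self, wt_params):
        traj = ChannelTrajectory(times=np.arange(5.0),
                                 states=np.zeros(5, dtype=np.int8), dt=1.0)
        with pytest.raises(ValueError):
            dwell_time_stats(traj)

    def test_ad_opens_longer_and_closes_shorter_than_wt(self, wt_params,
                                                        ad_params):
        ca, ip3 = 1.0, 10.0
        wt = dwell_time_stats(simulate_channel(ca, ip3, 0.0005, 20000.0,
                                               21, wt_params.ip3r))
        ad = dwell_time_stats(simulate_channel(ca, ip3, 0.0005, 20000.0,
                                               22, ad_params.ip3r))
        assert ad.tau_open > wt.tau_open
        assert ad.tau_closed < wt.tau_closed


@pytest.mark.parametrize("states, expected", [
    (np.zeros(10, dtype=int), 0.0),
    (np.array([2, 2, 2, 0, 1, 3, 0, 0, 0, 0]), 0.3),
    (np.array([2]), 1.0),
])
def test_cluster_open_fraction(states, expected):
    assert cluster_open_fraction(states) == pytest.approx(expected)
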