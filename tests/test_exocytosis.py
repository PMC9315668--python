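"""Vesicle pools, dual-sensor kinetics, refractoriness and fusion rates."""

import dataclasses

import numpy as np
import pytest

from boutonsim import (apply_refractoriness, pool_rhs, release_probability,
                       sensor_rhs, steady_state_spontaneous_rate)
from boutonsim.exocytosis import (IDX_R, IDX_U, IDX_V0, IDX_W0,
                                  equilibrium_sensor_distribution,
                                  fusion_hazard, initial_release_state,
                                  pool_totals, vesicle_total)
from boutonsim.kernel import run_release_clamp


class TestFusionHazards:
    def test_synchronous_rate_from_full_sensor(self, wt_params):
        hs, ha, hsp = fusion_hazard(5, 0, wt_params.release)
        assert hs == pytest.approx(2.000008, rel=1e-12)
        assert ha == 0.0 and hsp == 0.0

    def test_asynchronous_rate_is_a_times_gamma2(self, wt_params):
        _, ha, _ = fusion_hazard(3, 2, wt_params.release)
        assert ha == pytest.approx(0.025007 * 2.000008, rel=1e-12)
        assert ha == pytest.approx(0.05002, rel=1e-3)

    def test_spontaneous_only_from_ligand_free_state(self, wt_params):
        _, _, hsp = fusion_hazard(0, 0, wt_params.release)
        assert hsp == pytest.approx(9e-6, rel=1e-12)
        assert fusion_hazard(1, 0, wt_params.release)[2] == 0.0

    def test_cooperative_backward_rate_arithmetic(self, wt_params):
        # unbinding from m = 2: 2 * beta * b = 2 * 2.32 * 0.250007
        occ = np.zeros((6, 3))
        occ[2, 0] = 1.0
        d, _ = sensor_rhs(occ, 0.0, wt_params.release)
        assert d[1, 0] == pytest.approx(2 * 2.32 * 0.250007, rel=1e-12)
        assert d[1, 0] == pytest.approx(1.160, rel=1e-3)


class TestPoolKinetics:
    def test_zero_calcium_only_backward_rates(self, wt_params):
        y = initial_release_state(wt_params.release)
        d = pool_rhs(y, 0.0, 0.0, wt_params.release)
        # no mobilisation, no priming, no attachment: R can only gain
        assert d[IDX_R] >= 0
        assert d[IDX_U] >= 0           # unpriming inflow only
        assert d[IDX_W0:IDX_W0 + 18].sum() <= 0

    def test_priming_balance_with_site_gating(self, wt_params):
        rel = wt_params.release
        c = 0.5
        y = np.zeros(42)
        y[IDX_U] = 1.0
        y[IDX_V0] = 0.5
        free = rel.N_sites - 0.5
        d = pool_rhs(y, c, 0.0, rel)
        inflow = rel.kpriming * c * 1.0 * free / rel.N_sites
        # V(0,0) balance: priming in, unpriming + attachment(0) + sensor out
        expected = (inflow - rel.kunpr * 0.5
                    - 5 * rel.alpha * c * 0.5 - 2 * rel.lam * c * 0.5
                    - rel.gamma1 * 0.5)
        assert d[IDX_V0] == pytest.approx(expected, rel=1e-9)

    def test_mobilisation_linear_in_kmob(self, wt_params):
        rel2 = dataclasses.replace(wt_params.release,
                                   kmob=2 * wt_params.release.kmob)
        y = np.zeros(42)
        y[IDX_R] = 100.0
        d1 = pool_rhs(y, 0.3, 0.0, wt_params.release)
        d2 = pool_rhs(y, 0.3, 0.0, rel2)
        assert d2[IDX_U] == pytest.approx(2 * d1[IDX_U], rel=1e-12)

    def test_vesicles_conserved_by_mass_action(self, wt_params, rng):
        y = rng.uniform(0.0, 1.0, 42)
        d = pool_rhs(y, 0.4, 3.0, wt_params.release)
        # d(R + U + V + W + cumulative released)/dt = 0
        total_rate = (d[IDX_R] + d[IDX_U] + d[IDX_V0:IDX_V0 + 18].sum()
                      + d[IDX_W0:IDX_W0 + 18].sum() + d[39:42].sum())
        assert total_rate == pytest.approx(0.0, abs=1e-12)


class TestSensorRHS:
    def test_mass_lost_only_to_fusion(self, wt_params, rng):
        occ = rng.uniform(0, 1, (6, 3))
        d, rates = sensor_rhs(occ, 2.0, wt_params.release)
        assert d.sum() == pytest.approx(-sum(rates), abs=1e-12)

    def test_invalid_inputs(self, wt_params):
        with pytest.raises(ValueError):
            sensor_rhs(np.zeros((5, 3)), 1.0, wt_params.release)
        with pytest.raises(ValueError):
            sensor_rhs(np.full((6, 3), -1.0), 1.0, wt_params.release)


class TestRefractoriness:
    def test_no_fusion_no_change(self, wt_params, rng):
        sites = np.array([0, 1, 1, 0])
        out = apply_refractoriness(sites, np.zeros(4, bool),
                                   wt_params.release, 0.1, rng)
        assert np.array_equal(out, sites)

    def test_fused_sites_become_refractory(self, wt_params, rng):
        sites = np.array([1, 1, 0, 2])
        fused = np.array([True, False, False, False])
        out = apply_refractoriness(sites, fused, wt_params.release, 0.1, rng)
        assert out[0] == 2

    def test_expected_refractory_dwell_is_inverse_kRF(self, wt_params, rng):
        # geometric recovery with per-step hazard 1 - exp(-kRF dt):
        # mean dwell 1/kRF = 100 ms at the default kRF = 0.01/ms
        rel = wt_params.release
        dt = 1.0
        n = 20000
        sites = np.full(n, 2)
        dwell = np.zeros(n)
        alive = np.ones(n, bool)
        for step in range(1, 2000):
            out = apply_refractoriness(sites, np.zeros(n, bool), rel, dt,
                                       rng)
            recovered = alive & (out == 0)
            dwell[recovered] = step * dt
            alive &= out != 0
            sites = out
            if not alive.any():
                break
        # discrete-time mean is dt/(1-exp(-kRF dt)) ~ 100.5 ms
        assert dwell[dwell > 0].mean() == pytest.approx(100.5, rel=0.05)


class TestReleaseProbability:
    def test_bounds_and_errors(self):
        assert release_probability(0, 8) == 0.0
        assert release_probability(8, 8) == 1.0
        with pytest.raises(ValueError):
            release_probability(1, 0)


class TestSpontaneousRate:
    def test_resting_rate_in_reported_window(self, wt_params):
        r = steady_state_spontaneous_rate(0.1, wt_params.release)
        assert 1e-5 <= r <= 1e-4

    def test_zero_gamma1_gives_zero(self, wt_params):
        rel = dataclasses.replace(wt_params.release, gamma1=0.0)
        assert steady_state_spontaneous_rate(0.1, rel) == 0.0

    def test_linear_in_rrp_mass(self, wt_params):
        r1 = steady_state_spontaneous_rate(0.1, wt_params.release,
                                           rrp_size=4.0)
        r2 = steady_state_spontaneous_rate(0.1, wt_params.release,
                                           rrp_size=8.0)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_equilibrium_distribution_normalised(self, wt_params):
        occ = equilibrium_sensor_distribution(0.5, wt_params.release)
        assert occ.sum() == pytest.approx(1.0, abs=1e-12)
        assert (occ >= 0).all()


class TestDeterministicVsStochastic:
    """Mass-action ODE vs an independent per-vesicle Monte Carlo.

    The Monte Carlo is implemented here (vectorised, one uniform per site
    and step) and shares nothing with the kernel's jump-process code; both
    are driven by the same clamped Ca2+ waveform.
    """

    def _mc_cumulative_release(self, rel, ca, T, dt, trials, seed):
        rng = np.random.default_rng(seed)
        n = rel.N_sites
        m = np.zeros((trials, n), np.int64)
        a = np.zeros((trials, n), np.int64)
        alive = np.ones((trials, n), bool)
        released = np.zeros(trials)
        b = rel.b
        for _ in range(int(T / dt)):
            s_on = (5 - m) * rel.alpha * ca
            s_off = np.where(m > 0, m * rel.beta * b ** np.maximum(m - 1, 0),
                             0.0)
            a_on = (2 - a) * rel.lam * ca
            a_off = np.where(a > 0, a * rel.delta * b ** np.maximum(a - 1, 0),
                             0.0)
            hs = np.where(m == 5, rel.gamma2, 0.0)
            ha = np.where(a == 2, rel.a * rel.gamma2, 0.0)
            hsp = np.where((m == 0) & (a == 0), rel.gamma1, 0.0)
            tot = (s_on + s_off + a_on + a_off + hs + ha + hsp) * alive
            u = rng.random((trials, n)) / dt
            x = u.copy()
            fuse = x < hs + ha + hsp
            x -= hs + ha + hsp
            up_m = ~fuse & (x < s_on)
            x -= s_on
            dn_m = ~fuse & ~up_m & (x < s_off)
            x -= s_off
            up_a = ~fuse & ~up_m & ~dn_m & (x < a_on)
            x -= a_on
            dn_a = ~fuse & ~up_m & ~dn_m & ~up_a & (x < a_off)
            fuse &= alive
            released += fuse.sum(axis=1)
            alive &= ~fuse
            m += np.where(alive & up_m, 1, 0) - np.where(alive & dn_m, 1, 0)
            a += np.where(alive & up_a, 1, 0) - np.where(alive & dn_a, 1, 0)
        return released

    def test_mean_cumulative_release_agrees(self, wt_params):
        rel = dataclasses.replace(wt_params.release, kmob=1e-300,
                                  kpriming=1e-300, kattach=1e-300,
                                  kdetach=1e-300, kunpr=1e-300)
        ca, T, dt = 2.0, 20.0, 0.01   # partial release: ~0.5 of 8 fuse
        y0 = np.zeros(42)
        y0[IDX_V0] = float(rel.N_sites)    # all vesicles primed, detached
        times, rates, pools = run_release_clamp(rel.as_array(), y0, ca, ca,
                                                dt, int(T / dt), 10)
        det = pools[-1, 4]
        trials = 300
        mc = self._mc_cumulative_release(rel, ca, T, dt, trials, seed=5)
        se = mc.std(ddof=1) / np.sqrt(trials)
        assert abs(mc.mean() - det) < 3 * se + 1e-9


def test_initial_state_is_fully_primed(wt_params):
    y = initial_release_state(wt_params.release)
    t = pool_totals(y)
    assert t["V"] + t["W"] == pytest.approx(wt_params.release.N_sites)
    assert vesicle_total(y) == pytest.approx(
        t["R"] + t["U"] + wt_params.release.N_sites)
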