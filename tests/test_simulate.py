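"""Hybrid integrator contracts and experiment drivers."""

import numpy as np
import pytest

from boutonsim import (StimulusProtocol, integrate_hybrid, make_protocol,
                       run_ca_clamp, transient_metrics)
from boutonsim.exocytosis import initial_release_state
from boutonsim.kernel import run_release_clamp
from boutonsim.simulate import scoring_windows


class TestIntegratorContracts:
    def test_same_seed_bit_identical(self, wt_params):
        kw = dict(protocol=make_protocol("single"), T=70.0, seed=42,
                  n_vgcc=35)
        a = integrate_hybrid(wt_params, **kw)
        b = integrate_hybrid(wt_params, **kw)
        assert np.array_equal(a.df.to_numpy(), b.df.to_numpy())
        assert a.events.equals(b.events)

    def test_different_seeds_differ(self, wt_params):
        a = integrate_hybrid(wt_params, make_protocol("single"), T=70.0,
                             seed=1, n_vgcc=35)
        b = integrate_hybrid(wt_params, make_protocol("single"), T=70.0,
                             seed=2, n_vgcc=35)
        assert not np.array_equal(a.df["Po_VGCC"].to_numpy(),
                                  b.df["Po_VGCC"].to_numpy())

    def test_no_stimulation_no_ap(self, wt_params):
        quiet = StimulusProtocol(onsets_ms=np.array([1e9]), amplitude=0.0)
        tr = integrate_hybrid(wt_params, quiet, T=500.0, seed=8, n_vgcc=35)
        assert tr.ap_times.size == 0

    def test_single_pulse_single_ap(self, wt_params):
        tr = integrate_hybrid(wt_params, make_protocol("single"), T=120.0,
                              seed=4, n_vgcc=35)
        assert tr.ap_times.size == 1
        assert 50.0 < tr.ap_times[0] < 55.0

    def test_gating_variables_stay_in_unit_interval(self, wt_params):
        tr = integrate_hybrid(wt_params, make_protocol("paired"), T=150.0,
                              seed=5, n_vgcc=35)
        for col in ("n_gate", "h_gate"):
            x = tr.df[col].to_numpy()
            assert x.min() >= 0.0 and x.max() <= 1.0

    def test_concentrations_nonnegative(self, wt_params):
        tr = integrate_hybrid(wt_params, make_protocol("single"), T=120.0,
                              seed=6, n_vgcc=120)
        for col in ("Ca_cyt_uM", "Ca_IPRn_uM", "Ca_AZ_uM", "Ca_total_uM",
                    "IP3_uM"):
            assert tr.df[col].min() >= 0.0


class TestRK4Order:
    def test_halving_dt_shrinks_error_fourth_order(self, wt_params):
        # deterministic release subsystem under clamped Ca: no channel
        # noise, so the global error must scale ~dt^4
        rel = wt_params.release.as_array()
        y0 = initial_release_state(wt_params.release)
        ca, T = 5.0, 5.0

        def final(dt):
            _, _, pools = run_release_clamp(rel, y0, ca, ca, dt,
                                            int(round(T / dt)),
                                            int(round(T / dt)))
            return pools[-1, 4]

        ref = final(0.0025)
        e1 = abs(final(0.04) - ref)
        e2 = abs(final(0.02) - ref)
        assert e1 / max(e2, 1e-300) == pytest.approx(16.0, rel=0.7)


class TestCaClamp:
    def test_dose_response_trends(self, wt_params):
        res = run_ca_clamp([1.0, 3.0, 10.0, 30.0, 100.0], wt_params)
        assert np.all(np.diff(res.peak_rate) >= -1e-12)
        assert np.all(np.diff(res.time_to_peak) <= 1e-9)

    def test_zero_clamp_spontaneous_only(self, wt_params):
        res = run_ca_clamp([0.0], wt_params, T=50.0)
        times, total = res.profiles[0]
        gamma1 = wt_params.release.gamma1
        assert total.max() <= gamma1 * wt_params.release.N_sites * 1.01
        # flat profile: no transient above the spontaneous floor
        assert total.std() < gamma1

    def test_transient_decays_within_tens_of_ms(self, wt_params):
        res = run_ca_clamp([100.0], wt_params, T=100.0)
        times, total = res.profiles[0]
        ipk = int(np.argmax(total))
        late = total[times > times[ipk] + 50.0]
        assert late.max() < 0.05 * total[ipk]

    def test_negative_level_rejected(self, wt_params):
        with pytest.raises(ValueError):
            run_ca_clamp([-1.0], wt_params)


class TestTransientMetrics:
    def test_flat_trace_zero_areas(self):
        t = np.linspace(0.0, 10.0, 101)
        rate = np.zeros_like(t)
        rate[50] = 1.0
        ca = np.full_like(t, 0.05)
        m = transient_metrics(t, rate, ca, (0.0, 10.0), ca_az_rest=0.05)
        assert m.cumulative_ca == 0.0
        assert m.residual_ca == 0.0

    def test_residual_never_exceeds_cumulative(self, rng):
        t = np.linspace(0.0, 20.0, 401)
        rate = np.exp(-0.5 * (t - 5.0) ** 2)
        ca = 0.05 + np.abs(rng.normal(0, 1, t.size))
        m = transient_metrics(t, rate, ca, (0.0, 20.0), ca_az_rest=0.05)
        assert m.residual_ca <= m.cumulative_ca + 1e-12

    def test_empty_window_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            transient_metrics(t, t, t, (5.0, 6.0))


class TestScoringWindows:
    def test_interpulse_windows_with_final_extension(self):
        proto = make_protocol("paired")
        wins = scoring_windows(proto)
        assert wins == [(50.0, 90.0), (90.0, 140.0)]

    def test_train_windows_cover_every_pulse(self):
        proto = make_protocol("train")
        wins = scoring_windows(proto)
        assert len(wins) == 20
        assert wins[0] == (50.0, 100.0)
        assert wins[-1] == (1000.0, 1050.0)
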