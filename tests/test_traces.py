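"""Trace smoothing, onset/peak/half-decay extraction, spontaneous flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lenscalcium import traces as tm
from lenscalcium.synthetic import pulse_peak_time
from conftest import small_config
from lenscalcium import generate_capsule, analyze_capsule, summarize_capsule


class TestSmoothing:
    def test_constant_series_preserved(self):
        u = np.full(50, 3.7)
        for m in (0, 1, 3):
            np.testing.assert_allclose(tm.smooth_trace(u, m), u)

    def test_m1_excludes_center_sample(self):
        # middle of [0, 1, 0] -> (0 + 0)/2 = 0: the spike is removed
        out = tm.smooth_trace(np.array([0.0, 1.0, 0.0]), 1)
        assert out[1] == 0.0

    def test_m0_is_identity(self, rng):
        u = rng.normal(size=40)
        np.testing.assert_array_equal(tm.smooth_trace(u, 0), u)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            tm.smooth_trace(np.ones(4), 2)

    @given(st.integers(0, 4), st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_variance_non_increasing(self, m, seed):
        u = np.random.default_rng(seed).normal(size=60)
        assert tm.smooth_trace(u, m).var() <= u.var() + 1e-12

    def test_boundary_window_truncates_symmetrically(self):
        u = np.arange(10.0)
        out = tm.smooth_trace(u, 3)
        # sample 1 can only use m'=1: (u[0] + u[2])/2
        assert out[1] == pytest.approx((u[0] + u[2]) / 2)
        assert out[0] == u[0]  # no symmetric window at the very edge


class TestDetectResponse:
    times = np.arange(300.0)

    def test_flat_trace_is_nonresponder(self):
        ok, t = tm.detect_response(np.ones(300), self.times, 120.0)
        assert not ok and math.isnan(t)

    def test_noise_free_step_onset_exact(self):
        u = np.where(self.times >= 120, 2.0, 1.0)
        ok, t_res = tm.detect_response(u, self.times, 120.0)
        assert ok and t_res == 120.0

    def test_small_amplitude_excluded(self):
        u = np.where(self.times >= 120, 1.04, 1.0)  # below min_amplitude=0.05
        ok, _ = tm.detect_response(u, self.times, 120.0)
        assert not ok

    def test_t_stim_outside_recording_raises(self):
        with pytest.raises(ValueError):
            tm.detect_response(np.ones(300), self.times, 500.0)


class TestExtractEventTimes:
    def test_double_exponential_peak_closed_form(self):
        times = np.arange(0.0, 400.0)
        rise, decay, on = 4.0, 30.0, 120.0
        dt = np.maximum(times - on, 0)
        u = 1 + 0.5 * (1 - np.exp(-dt / rise)) * np.exp(-dt / decay) \
            * (times >= on)
        ev = tm.extract_event_times(u, times, 120.0, 100.0)
        assert ev.t_max == pytest.approx(on + pulse_peak_time(rise, decay),
                                         abs=1.0)

    def test_triangular_pulse_geometry(self):
        times = np.arange(0.0, 300.0)
        u = np.interp(times, [0, 120, 130, 140, 299], [0, 0, 1, 0, 0])
        ev = tm.extract_event_times(u, times, 120.0, 100.0)
        assert ev.dt_act == pytest.approx(10.0)
        assert ev.dt_deact == pytest.approx(5.0)  # half-height on the descent

    def test_never_decaying_trace_flagged(self):
        times = np.arange(0.0, 300.0)
        u = np.where(times >= 120, (times - 120) / 180, 0.0)
        ev = tm.extract_event_times(u, times, 120.0, 100.0)
        assert ev.deact_excluded and math.isnan(ev.t_half)

    def test_ordering_invariant_on_synthetic_capsule(self, capsule):
        for ev in analyze_capsule(capsule):
            if ev.is_responder:
                assert ev.t_res <= ev.t_max
                if not ev.deact_excluded:
                    assert ev.t_max <= ev.t_half
                    assert ev.dt_deact >= 0
                assert ev.dt_act >= 0


class TestDetectSpontaneous:
    times = np.arange(300.0)

    def test_quiet_baseline_not_flagged(self, rng):
        u = 1 + 0.005 * rng.normal(size=300)
        u[150:] += 0.5  # the evoked response must not count
        assert not tm.detect_spontaneous(u, self.times, 120.0)

    def test_injected_prestimulus_pulse_flagged(self, rng):
        u = 1 + 0.005 * rng.normal(size=300)
        u[50:55] += 0.5  # 10x MAD, 5 samples wide
        assert tm.detect_spontaneous(u, self.times, 120.0)

    def test_short_prestimulus_segment_raises(self):
        assert_times = np.arange(40.0)
        with pytest.raises(ValueError):
            tm.detect_spontaneous(np.ones(40), assert_times, 10.0)


class TestSummary:
    def _ev(self, cid, dt_act=15.0, spont=False):
        return tm.CellEventTimes(cell_id=cid, is_responder=True,
                                 is_spontaneous=spont, t_res=100.0,
                                 t_max=100.0 + dt_act,
                                 t_half=100.0 + dt_act + 20.0)

    def test_spontaneous_fraction(self):
        evs = [self._ev(f"c{i}", spont=i < 2) for i in range(10)]
        s = summarize_capsule(evs)
        assert s.frac_spontaneous == pytest.approx(0.2)

    def test_mean_dt_act(self):
        evs = [self._ev("a", 10.0), self._ev("b", 20.0), self._ev("c", 30.0)]
        assert summarize_capsule(evs).mean_dt_act == pytest.approx(20.0)

    def test_nonresponders_excluded_from_means(self):
        evs = [self._ev("a", 15.0),
               tm.CellEventTimes(cell_id="b", is_responder=False)]
        s = summarize_capsule(evs)
        assert s.mean_dt_act == pytest.approx(15.0)
        assert s.n_responders == 1 and s.n_cells == 2

    def test_zero_responders_gives_nan_means(self):
        evs = [tm.CellEventTimes(cell_id="b", is_responder=False)]
        s = summarize_capsule(evs)
        assert math.isnan(s.mean_dt_act)


def test_noise_free_capsule_recovers_ground_truth_within_one_frame():
    cfg = small_config(noise_sd=0.0, spont_cluster_count=0,
                       frac_nonresponder=0.0, seed=21)
    rec = generate_capsule(cfg)
    gt = rec.ground_truth
    events = analyze_capsule(rec, tm.TraceConfig(smooth_m=0))
    t_peak = pulse_peak_time(cfg.rise_tau, cfg.decay_tau)
    for i, ev in enumerate(events):
        assert ev.is_responder
        # detection threshold sits a hair above baseline when noise-free
        assert abs(ev.t_res - gt.t_on[i]) <= 1.0 + cfg.frame_dt
        assert abs(ev.t_max - (gt.t_on[i] + t_peak)) <= 1.0 + cfg.frame_dt
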