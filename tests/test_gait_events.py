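import numpy as np
import pytest

from adaptkit.gait import (
    ForceTrace,
    GaitEvents,
    MarkerTrace,
    compute_step_lengths,
    detect_heel_strikes,
    lowpass_filter_zero_lag,
)


class TestLowpassFilter:
    def test_dc_preserved(self):
        x = np.full(2000, 3.7)
        assert np.allclose(lowpass_filter_zero_lag(x, 4, 300.0, 1000.0), x)

    def test_passband_sinusoid_preserved(self):
        fs, f = 1000.0, 5.0
        t = np.arange(0, 4, 1 / fs)
        x = np.sin(2 * np.pi * f * t)
        y = lowpass_filter_zero_lag(x, 4, 300.0, fs)
        mid = slice(500, -500)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuation_matches_closed_form(self):
        # two-pass 4th-order Butterworth at 2x cutoff: |H|^2 = (1/(1+2^8))
        fs, cutoff = 1000.0, 100.0
        f = 2 * cutoff
        t = np.arange(0, 4, 1 / fs)
        x = np.sin(2 * np.pi * f * t)
        y = lowpass_filter_zero_lag(x, 4, cutoff, fs)
        bound = 1.0 / (1.0 + (f / cutoff) ** 8)  # squared single-pass magnitude
        mid = slice(1000, -1000)
        assert np.max(np.abs(y[mid])) <= bound * 1.05

    def test_cutoff_at_nyquist_refused(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_filter_zero_lag(np.zeros(100), 4, 300.0, 100.0)


def square_force(n, events, fs=1000.0, high=400.0, width=300):
    f = np.zeros(n)
    for e in events:
        f[e:e + width] = high
    return f


class TestDetectHeelStrikes:
    def test_square_wave_exact_indices(self):
        events = [500, 1600, 2700]
        vgrf = ForceTrace(fast=square_force(4000, events),
                          slow=square_force(4000, [1000, 2100, 3200]))
        out = detect_heel_strikes(vgrf, threshold=20.0)
        assert list(out.fast) == events
        assert list(out.slow) == [1000, 2100, 3200]

    def test_subthreshold_jitter_single_event_per_stance(self):
        # double-bump stance: sub-threshold wobble before loading must not
        # create extra events
        fs = 1000.0
        f = np.zeros(3000)
        f[480:500] = 15.0            # jitter below 20 N
        f[500:800] = 400.0           # loading
        f[650:700] = 350.0           # mid-stance dip stays above threshold
        f[1700:2000] = 400.0
        vgrf = ForceTrace(fast=f, slow=np.zeros(3000))
        with pytest.warns(UserWarning):
            pass_events = detect_heel_strikes(ForceTrace(fast=np.zeros(10),
                                                         slow=np.zeros(10)))
        out = detect_heel_strikes(vgrf, threshold=20.0, refractory=0.2)
        assert list(out.fast) == [500, 1700]

    def test_all_zero_force_warns_empty(self):
        vgrf = ForceTrace(fast=np.zeros(1000), slow=np.zeros(1000))
        with pytest.warns(UserWarning, match="no heel strikes"):
            out = detect_heel_strikes(vgrf)
        assert out.fast.size == 0 and out.slow.size == 0

    def test_nonincreasing_indices_refused(self):
        with pytest.raises(ValueError, match="increasing"):
            GaitEvents(fast=np.array([10, 10]), slow=np.array([]))


class TestComputeStepLengths:
    def test_hand_case(self):
        heel_fast = MarkerTrace(ap=np.full(200, 350.0))
        heel_slow = MarkerTrace(ap=np.full(200, -250.0))
        ev = GaitEvents(fast=np.array([500]), slow=np.array([]), fs=1000.0)
        sf, ss, info = compute_step_lengths(heel_fast, heel_slow, ev)
        assert sf[0] == pytest.approx(600.0)

    def test_colocated_heels_zero(self):
        m = MarkerTrace(ap=np.full(100, 123.0))
        ev = GaitEvents(fast=np.array([100]), slow=np.array([300]), fs=1000.0)
        sf, ss, _ = compute_step_lengths(m, m, ev)
        assert sf[0] == 0.0 and ss[0] == 0.0

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(0)
        base_f = 300 + 50 * np.sin(np.linspace(0, 6, 500))
        base_s = -200 + 40 * np.cos(np.linspace(0, 6, 500))
        ev = GaitEvents(fast=np.array([1000, 2500]), slow=np.array([1700]),
                        fs=1000.0)
        sf0, ss0, _ = compute_step_lengths(MarkerTrace(ap=base_f),
                                           MarkerTrace(ap=base_s), ev)
        off = 1234.5
        sf1, ss1, _ = compute_step_lengths(MarkerTrace(ap=base_f + off),
                                           MarkerTrace(ap=base_s + off), ev)
        assert np.allclose(sf0, sf1) and np.allclose(ss0, ss1)

    def test_sinusoid_closed_form(self):
        fs_m = 100.0
        t = np.arange(0, 5, 1 / fs_m)
        heel_fast = MarkerTrace(ap=300 * np.sin(2 * np.pi * 0.5 * t), fs=fs_m)
        heel_slow = MarkerTrace(ap=-300 * np.sin(2 * np.pi * 0.5 * t), fs=fs_m)
        ev_t = 1.23  # seconds; force sampled at 1000 Hz
        ev = GaitEvents(fast=np.array([int(ev_t * 1000)]), slow=np.array([]),
                        fs=1000.0)
        sf, _, _ = compute_step_lengths(heel_fast, heel_slow, ev)
        expected = 600 * np.sin(2 * np.pi * 0.5 * ev_t)
        # linear interpolation error of a 0.5 Hz sinusoid at 100 Hz is tiny
        assert sf[0] == pytest.approx(expected, abs=0.2)

    def test_event_outside_trace_skipped_and_counted(self):
        m = MarkerTrace(ap=np.zeros(100), fs=100.0)  # 1 s of markers
        ev = GaitEvents(fast=np.array([500, 5000]), slow=np.array([]),
                        fs=1000.0)
        sf, _, info = compute_step_lengths(m, m, ev)
        assert sf.size == 1
        assert info["skipped"]["fast"] == 1


class TestRoundTrip:
    def test_known_step_lengths_recovered(self):
        """Fixture built from known step lengths round-trips through
        detection + marker interpolation within interpolation error."""
        fs_f, fs_m = 1000.0, 100.0
        stride_t = 1.0
        n_strides = 8
        known_fast = 600.0 + 10 * np.arange(n_strides)
        dur = (n_strides + 1) * stride_t
        tm = np.arange(0, dur, 1 / fs_m)
        # fast heel strikes at t = 1, 2, ...; build AP traces that realize the
        # desired between-heel distance at those instants
        heel_fast = 300.0 * np.ones_like(tm)
        heel_slow_vals = np.interp(
            tm, np.arange(1, n_strides + 1) * stride_t, 300.0 - known_fast)
        force = np.zeros(int(dur * fs_f))
        idx = (np.arange(1, n_strides + 1) * stride_t * fs_f).astype(int)
        for i in idx:
            force[i:i + 300] = 500.0
        vgrf = ForceTrace(fast=force, slow=np.zeros_like(force))
        events = detect_heel_strikes(vgrf)
        sf, _, _ = compute_step_lengths(MarkerTrace(ap=heel_fast, fs=fs_m),
                                        MarkerTrace(ap=heel_slow_vals, fs=fs_m),
                                        events)
        assert np.allclose(sf, known_fast, atol=0.5)
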