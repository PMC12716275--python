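"""Spindle/slow-wave detection and phase-locking."""

import numpy as np
import pytest
from scipy import signal

import sleepwarp as sw
from sleepwarp.core import BandPowerSeries, Hypnogram, Recording, SpindleEvent

FS = 207.0


def _make_burst_signal(bursts, dur_s=240.0, noise_amp=3.0, seed=0, freq=13.0):
    """Background noise plus 13 Hz bursts at given (onset, dur, amp)."""
    rng = np.random.default_rng(seed)
    n = int(dur_s * FS)
    t = np.arange(n) / FS
    sos = signal.butter(2, 35 / (FS / 2), btype="low", output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    x *= noise_amp / x.std()
    for onset, dur, amp in bursts:
        a, b = int(onset * FS), int((onset + dur) * FS)
        x[a:b] += amp * signal.windows.tukey(b - a, 0.25) * np.sin(2 * np.pi * freq * t[a:b])
    return Recording(x, fs=FS)


def _all_n2(dur_s=240.0):
    return Hypnogram(np.array(["N2"] * int(dur_s / 30), dtype=object))


class TestSpindleDetection:
    def test_recovers_planted_bursts(self):
        bursts = [(20 + 10 * k, 1.2, 40.0) for k in range(20)]
        rec = _make_burst_signal(bursts)
        events = sw.detect_spindles(rec, _all_n2())
        assert len(events) == 20
        for e, (onset, dur, _) in zip(events, bursts):
            assert abs(e.onset_s - onset) <= 0.25

    def test_too_short_burst_not_reported(self):
        rec = _make_burst_signal([(30.0, 0.3, 40.0), (60.0, 1.2, 40.0)])
        events = sw.detect_spindles(rec, _all_n2())
        assert len(events) == 1
        assert abs(events[0].onset_s - 60.0) < 0.3

    def test_overlapping_candidates_both_discarded(self):
        # two distinct 5x cores bridged by an intermediate-amplitude segment
        # (above 3x, below 5x): their extended extents coincide -> overlap
        rec = _make_burst_signal(
            [(30.0, 0.7, 40.0), (30.5, 1.0, 8.0), (31.2, 0.7, 40.0), (60.0, 1.2, 40.0)]
        )
        events = sw.detect_spindles(rec, _all_n2())
        assert all(abs(e.onset_s - 30.0) > 2.0 for e in events)
        assert any(abs(e.onset_s - 60.0) < 0.3 for e in events)

    def test_scale_invariance(self):
        """Mean-relative thresholds: rescaling the signal changes nothing."""
        rec = _make_burst_signal([(20 + 12 * k, 1.2, 40.0) for k in range(15)])
        events1 = sw.detect_spindles(rec, _all_n2())
        rec2 = Recording(rec.samples * 7.3, fs=FS)
        events2 = sw.detect_spindles(rec2, _all_n2())
        assert [(e.onset_s, e.offset_s) for e in events1] == [
            (e.onset_s, e.offset_s) for e in events2
        ]

    def test_no_outputs_overlap_and_durations_bounded(self, deep_hypnogram, raw_night):
        events = sw.detect_spindles(raw_night[0], deep_hypnogram)
        for a, b in zip(events, events[1:]):
            assert a.offset_s <= b.onset_s
        assert all(0.5 <= e.duration_s <= 2.5 for e in events)

    def test_planted_spindles_recovered_with_high_precision_recall(
        self, deep_hypnogram, raw_night
    ):
        rec, planted, _ = raw_night
        detected = sw.detect_spindles(rec, deep_hypnogram)
        onsets = np.array([e.onset_s for e in detected])
        tp = sum(1 for g in planted if onsets.size and np.min(np.abs(onsets - g.onset_s)) <= 0.25)
        assert tp / len(planted) >= 0.9
        assert tp / len(detected) >= 0.9

    def test_no_deep_sleep_warns_and_returns_empty(self):
        rec = _make_burst_signal([(30.0, 1.2, 40.0)])
        hyp = Hypnogram(np.array(["REM"] * 8, dtype=object))
        with pytest.warns(UserWarning, match="N2/N3"):
            assert sw.detect_spindles(rec, hyp) == []


class TestIntervals:
    def test_simple_differencing(self):
        events = [SpindleEvent(o, o + 1.0) for o in (0.0, 4.5, 9.0)]
        iv, _, _ = sw.inter_spindle_intervals(events)
        assert np.allclose(iv, [4.5, 4.5])

    def test_intervals_never_span_rem_blocks(self):
        labels = ["N2"] * 10 + ["REM"] * 10 + ["N2"] * 10
        hyp = Hypnogram(np.array(labels, dtype=object))
        events = [SpindleEvent(o, o + 1.0) for o in (100.0, 140.0, 700.0, 745.0)]
        iv, _, _ = sw.inter_spindle_intervals(events, hyp)
        assert np.allclose(sorted(iv), [40.0, 45.0])

    def test_fewer_than_two_events_raises(self):
        with pytest.raises(ValueError, match="2"):
            sw.inter_spindle_intervals([SpindleEvent(0.0, 1.0)])


class TestSlowWaves:
    def test_pure_sinusoid_event_per_cycle(self):
        t = np.arange(int(120 * FS)) / FS
        rec = Recording(60.0 * np.sin(2 * np.pi * 1.0 * t), fs=FS)
        hyp = Hypnogram(np.array(["N3"] * 4, dtype=object))
        events = sw.detect_slow_waves(rec, hyp, amp_percentile=0.0)
        assert 110 <= len(events) <= 120
        assert all(e.trough_s < e.peak_s for e in events)

    def test_flat_signal_empty(self):
        rec = Recording(np.zeros(int(60 * FS)), fs=FS)
        hyp = Hypnogram(np.array(["N3"] * 2, dtype=object))
        assert sw.detect_slow_waves(rec, hyp) == []

    def test_planted_slow_waves_recovered(self, deep_hypnogram, raw_night):
        rec, _, truth = raw_night
        events = sw.detect_slow_waves(rec, deep_hypnogram)
        troughs = np.array([e.trough_s for e in events])
        hits = sum(
            1 for t, _, _ in truth["slow_waves"] if np.min(np.abs(troughs - t)) <= 0.3
        )
        assert hits / len(truth["slow_waves"]) >= 0.8


class TestPLV:
    def test_constant_phase_gives_unity(self):
        res = sw.spindle_sw_plv(np.full(50, np.pi / 3), None)
        assert res.plv == pytest.approx(1.0)
        assert res.preferred_phase == pytest.approx(np.pi / 3)

    def test_symmetric_phases_give_zero(self):
        res = sw.spindle_sw_plv(np.linspace(0, 2 * np.pi, 8, endpoint=False) + 0.3, None)
        assert res.plv == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(0)
        res = sw.spindle_sw_plv(rng.uniform(-np.pi, np.pi, 10_000), None)
        assert res.plv < 0.03

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        phases = rng.vonmises(0.5, 2.0, 200)
        r1 = sw.spindle_sw_plv(phases, None)
        r2 = sw.spindle_sw_plv(np.angle(np.exp(1j * (phases + 1.1))), None)
        assert r2.plv == pytest.approx(r1.plv, abs=1e-12)
        shift = np.angle(np.exp(1j * (r2.preferred_phase - r1.preferred_phase)))
        assert shift == pytest.approx(1.1, abs=1e-9)

    def test_event_api_samples_phase_at_onsets(self):
        t = np.arange(int(60 * FS)) / FS
        rec = Recording(30.0 * np.cos(2 * np.pi * 1.0 * t), fs=FS)
        phase_fn = sw.slow_wave_phase(rec)
        events = [SpindleEvent(o, o + 0.5) for o in np.arange(5.0, 45.0, 1.0)]
        res = sw.spindle_sw_plv(events, phase_fn)
        assert res.plv > 0.95  # onsets at integer seconds = cosine peaks
        assert abs(res.preferred_phase) < 0.2

    def test_too_few_events_raises_naming_minimum(self):
        events = [SpindleEvent(float(o), o + 0.5) for o in range(5)]
        with pytest.raises(ValueError, match="10"):
            sw.spindle_sw_plv(events, lambda t: np.zeros_like(t))


class TestSigmaDeltaTrajectory:
    def test_constant_series_constant_trajectory(self):
        bp = BandPowerSeries(np.ones((5, 100)))
        traj = sw.sigma_delta_trajectory(bp)
        assert np.allclose(traj[:, 1], 1.0)
        assert np.allclose(traj[:, 2], 1.0)

    def test_window_equal_to_series_gives_global_mean(self):
        rng = np.random.default_rng(0)
        bp = BandPowerSeries(rng.uniform(1, 2, (5, 25)))
        traj = sw.sigma_delta_trajectory(bp, window_min=5.0, step_min=1.0)
        assert traj.shape[0] == 1
        assert traj[0, 1] == pytest.approx(bp.band("sigma").mean())
        assert traj[0, 2] == pytest.approx(bp.band("delta").mean())

    def test_n2_to_n3_dynamics(self, night):
        """Within a planted N2->N3 segment, delta rises while sigma rises
        then falls."""
        st = night.hypnogram.stage_at(night.bandpower.times())
        traj = sw.sigma_delta_trajectory(night.bandpower)
        # locate a long N2 run followed by N3
        runs = []
        start = 0
        for i in range(1, len(st) + 1):
            if i == len(st) or st[i] != st[start]:
                runs.append((st[start], start, i))
                start = i
        seg = None
        for k in range(len(runs) - 1):
            if runs[k][0] == "N2" and runs[k + 1][0] == "N3" and runs[k][2] - runs[k][1] > 40:
                seg = (runs[k][1], runs[k + 1][2])
                break
        assert seg is not None
        t0, t1 = np.array(seg) * night.bandpower.bin_s
        sel = (traj[:, 0] >= t0) & (traj[:, 0] < t1)
        sig, dlt = traj[sel, 1], traj[sel, 2]
        assert dlt[-1] > dlt[0]  # delta builds up towards N3
        peak = np.argmax(sig)
        assert 0 < peak < len(sig) - 1  # sigma rises then falls

    def test_series_shorter_than_window_raises(self):
        bp = BandPowerSeries(np.ones((5, 10)))
        with pytest.raises(ValueError, match="window"):
            sw.sigma_delta_trajectory(bp, window_min=5.0)
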