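"""Sleep spindles, slow waves, and their phase relationship.

Spindle detection follows the mean-relative envelope rule: within N2/N3,
candidates are excursions of the 11-16 Hz envelope above 5x its N2/N3
mean, with boundaries extended outward to the 3x-mean crossings; events
overlapping another candidate or outside 0.5-2.5 s are discarded. Because
all thresholds are relative to the mean envelope, detection is invariant
to a global rescaling of the signal.

Slow waves are delimited by zero crossings of the 0.5-4 Hz trace
(negative half-waves of 0.25-1 s whose trough amplitude exceeds an
adaptive percentile threshold), and the spindle/slow-wave coupling is
summarised by the phase-locking value (PLV): the modulus of the circular
mean of unit phasors at spindle onsets, with phase 0 at the slow-wave
positive peak.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .core import (
    BandPowerSeries,
    Hypnogram,
    PhaseLockingResult,
    Recording,
    SlowWaveEvent,
    SpindleEvent,
)
from .synthgen import _sample_runs

__all__ = [
    "detect_spindles",
    "inter_spindle_intervals",
    "detect_slow_waves",
    "slow_wave_phase",
    "spindle_sw_plv",
    "sigma_delta_trajectory",
]


def _sigma_envelope(x: np.ndarray, fs: float, smooth_s: float = 0.1) -> np.ndarray:
    sos = signal.butter(4, [11.0 / (fs / 2.0), 16.0 / (fs / 2.0)], btype="band", output="sos")
    env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, x)))
    if smooth_s > 0:
        w = max(1, int(round(smooth_s * fs)))
        env = np.convolve(env, np.ones(w) / w, mode="same")
    return env


def detect_spindles(
    recording: Recording,
    hypnogram: Hypnogram,
    core_factor: float = 5.0,
    edge_factor: float = 3.0,
    min_dur_s: float = 0.5,
    max_dur_s: float = 2.5,
    overlap_action: str = "discard",
    min_separation_s: float = 0.3,
) -> list[SpindleEvent]:
    """Detect sleep spindles in N2/N3.

    The envelope mean is taken over N2/N3 samples only (the detection
    domain), per night. Above-core excursions separated by less than
    ``min_separation_s`` are treated as one waxing-waning event; beyond
    that, candidates sharing samples are overlapping and
    ``overlap_action='discard'`` drops *both* members of the pair (the
    literal duplicate-rejection rule) while ``'merge'`` fuses them.
    """
    if overlap_action not in ("discard", "merge"):
        raise ValueError("overlap_action must be 'discard' or 'merge'")
    x = np.atleast_1d(recording.samples)
    fs = recording.fs
    deep = hypnogram.sample_mask(fs, x.size, ("N2", "N3"))
    if not deep.any():
        warnings.warn("no N2/N3 epochs; returning no spindles", stacklevel=2)
        return []
    env = _sigma_envelope(x, fs)
    mean_env = env[deep].mean()
    core = (env > core_factor * mean_env) & deep
    above_edge = env > edge_factor * mean_env

    # fuse core excursions closer than min_separation_s (waxing-waning of
    # one event), then extend outward to the edge-factor crossings
    gap = int(round(min_separation_s * fs))
    cores: list[list[int]] = []
    for a, b in _sample_runs(core):
        if cores and a - cores[-1][1] < gap:
            cores[-1][1] = b
        else:
            cores.append([a, b])
    raw: list[tuple[int, int, float]] = []
    for a, b in cores:
        lo = a
        while lo > 0 and above_edge[lo - 1]:
            lo -= 1
        hi = b
        while hi < x.size and above_edge[hi]:
            hi += 1
        raw.append((lo, hi, float(env[lo:hi].max())))

    # overlap rule among distinct extended candidates
    keep: list[tuple[int, int, float]] = []
    n = len(raw)
    overlapping = [False] * n
    for i in range(n - 1):
        if raw[i + 1][0] < raw[i][1]:
            overlapping[i] = overlapping[i + 1] = True
    if overlap_action == "discard":
        keep = [r for r, o in zip(raw, overlapping) if not o]
    else:
        for r, o in zip(raw, overlapping):
            if keep and r[0] < keep[-1][1]:
                a, b, p = keep.pop()
                keep.append((a, max(b, r[1]), max(p, r[2])))
            else:
                keep.append(r)

    events: list[SpindleEvent] = []
    for a, b, peak in keep:
        dur = (b - a) / fs
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        seg = signal.sosfiltfilt(
            signal.butter(4, [11.0 / (fs / 2), 16.0 / (fs / 2)], btype="band", output="sos"),
            x[max(0, a - int(fs)) : min(x.size, b + int(fs))],
        )[a - max(0, a - int(fs)) : b - max(0, a - int(fs))]
        phase = np.unwrap(np.angle(signal.hilbert(seg)))
        mean_freq = float((phase[-1] - phase[0]) / (2 * np.pi * dur)) if seg.size > 1 else np.nan
        events.append(SpindleEvent(a / fs, b / fs, peak_amplitude=peak, mean_freq=mean_freq))
    events.sort(key=lambda e: e.onset_s)
    return events


def inter_spindle_intervals(
    events: list[SpindleEvent],
    hypnogram: Hypnogram | None = None,
    bin_width_s: float = 1.0,
    max_interval_s: float = 60.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Onset-to-onset intervals, restricted to contiguous N2/N3 runs.

    Returns ``(intervals, hist_counts, hist_edges)``; the histogram uses
    ``bin_width_s``-wide bins up to ``max_interval_s``.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 spindle events")
    onsets = np.asarray(sorted(e.onset_s for e in events))
    if hypnogram is not None:
        run_id = np.full(onsets.size, -1)
        t_epochs = hypnogram.stage_at(onsets)
        deep_epoch = np.isin(hypnogram.labels, ("N2", "N3"))
        runs = _sample_runs(deep_epoch)
        for rid, (a, b) in enumerate(runs):
            t0, t1 = a * hypnogram.epoch_s, b * hypnogram.epoch_s
            run_id[(onsets >= t0) & (onsets < t1)] = rid
        same_run = run_id[1:] == run_id[:-1]
        intervals = np.diff(onsets)[same_run & (run_id[1:] >= 0)]
        del t_epochs
    else:
        intervals = np.diff(onsets)
    edges = np.arange(0.0, max_interval_s + bin_width_s, bin_width_s)
    counts, edges = np.histogram(intervals, bins=edges)
    return intervals, counts, edges


def _slow_filtered(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(2, [0.5 / (fs / 2.0), 4.0 / (fs / 2.0)], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_slow_waves(
    recording: Recording,
    hypnogram: Hypnogram,
    amp_percentile: float = 75.0,
    min_half_s: float = 0.25,
    max_half_s: float = 1.0,
) -> list[SlowWaveEvent]:
    """Zero-crossing slow-wave detection on the 0.5-4 Hz trace.

    Candidate negative half-waves between successive zero crossings are
    kept when their duration lies in [min_half_s, max_half_s] and their
    trough amplitude exceeds the ``amp_percentile``-th percentile of all
    candidates (adaptive threshold). The event peak is the maximum of the
    following positive half-wave.
    """
    x = np.atleast_1d(recording.samples)
    fs = recording.fs
    deep = hypnogram.sample_mask(fs, x.size, ("N2", "N3"))
    if not deep.any():
        warnings.warn("no N2/N3 epochs; returning no slow waves", stacklevel=2)
        return []
    lf = _slow_filtered(x, fs)
    neg = (lf < 0) & deep
    candidates: list[tuple[int, int, float]] = []
    for a, b in _sample_runs(neg):
        dur = (b - a) / fs
        if min_half_s <= dur <= max_half_s:
            candidates.append((a, b, float(-lf[a:b].min())))
    if not candidates:
        return []
    amps = np.asarray([c[2] for c in candidates])
    thr = np.percentile(amps, amp_percentile)
    events: list[SlowWaveEvent] = []
    for a, b, amp in candidates:
        if amp <= thr:
            continue
        trough = a + int(np.argmin(lf[a:b]))
        # following positive half-wave peak
        hi = min(x.size, b + int(max_half_s * fs))
        seg = lf[b:hi]
        peak = b + int(np.argmax(seg)) if seg.size else b
        events.append(
            SlowWaveEvent(
                trough_s=trough / fs,
                peak_s=peak / fs,
                peak_to_peak=float(amp + max(lf[b:hi].max(), 0.0) if seg.size else amp),
            )
        )
    return events


def slow_wave_phase(recording: Recording):
    """Instantaneous slow-wave (0.5-4 Hz) phase as a callable t -> radians.

    Phase 0 corresponds to the positive peak of the filtered trace (the
    analytic-signal convention); the returned function interpolates the
    unwrapped phase and wraps to (-pi, pi].
    """
    x = np.atleast_1d(recording.samples)
    fs = recording.fs
    phase = np.unwrap(np.angle(signal.hilbert(_slow_filtered(x, fs))))
    times = np.arange(x.size) / fs

    def phase_at(t: np.ndarray | float) -> np.ndarray:
        p = np.interp(np.asarray(t, dtype=float), times, phase)
        return np.angle(np.exp(1j * p))

    return phase_at


def spindle_sw_plv(
    spindles: list[SpindleEvent] | np.ndarray,
    slow_phase,
    min_events: int = 10,
) -> PhaseLockingResult:
    """Phase-locking of spindle onsets to the slow-wave phase.

    ``spindles`` may be a list of events (phases are sampled at onsets via
    ``slow_phase``; the ``min_events`` floor applies) or an array of phases
    directly (``slow_phase`` ignored, no minimum enforced). PLV is the
    modulus of the mean unit phasor.
    """
    if isinstance(spindles, np.ndarray):
        phases = np.asarray(spindles, dtype=float)
        if phases.size == 0:
            raise ValueError("no phases given")
    else:
        if len(spindles) < min_events:
            raise ValueError(f"need at least {min_events} spindles for a PLV estimate")
        onsets = np.asarray([e.onset_s for e in spindles])
        phases = np.asarray(slow_phase(onsets), dtype=float)
    z = np.mean(np.exp(1j * phases))
    return PhaseLockingResult(
        plv=float(np.abs(z)), preferred_phase=float(np.angle(z)), n_events=int(phases.size)
    )


def sigma_delta_trajectory(
    series: BandPowerSeries,
    window_min: float = 5.0,
    step_min: float = 1.0,
) -> np.ndarray:
    """Sliding-window (sigma_mean, delta_mean) trajectory.

    Returns an array of rows ``(t_center_s, sigma_mean, delta_mean)``;
    means are over valid bins only. Raises if the series is shorter than
    one window.
    """
    win = int(round(window_min * 60.0 / series.bin_s))
    step = max(1, int(round(step_min * 60.0 / series.bin_s)))
    if series.n_bins < win:
        raise ValueError("series shorter than the sliding window")
    sig = series.band("sigma")
    dlt = series.band("delta")
    rows = []
    for a in range(0, series.n_bins - win + 1, step):
        sel = series.valid[a : a + win]
        if not sel.any():
            continue
        rows.append(
            (
                (a + win / 2.0) * series.bin_s,
                float(sig[a : a + win][sel].mean()),
                float(dlt[a : a + win][sel].mean()),
            )
        )
    return np.asarray(rows)
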