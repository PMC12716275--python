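"""Synthetic multi-subject, multi-night sleep cohorts.

The study's raw sub-scalp EEG is proprietary, so this module generates
cohorts with the statistical structure the downstream analyses assume:

* a semi-Markov hypnogram process producing 3-5 NREM-REM cycles per night
  with a shorter first and longer second cycle, ~25 % REM, and brief
  awakenings;
* stage-conditioned log-normal band powers with slow-wave (delta)
  homeostatic decline across cycles, within-N2 sigma ramp-up, within-N3
  sigma decay against a delta plateau, and a transient sigma surge in the
  minutes before each REM onset;
* optional raw EEG at 207 Hz containing discrete spindle bursts planted in
  infra-slow-gated trains (~4-5 s within-train intervals, ~40-50 s train
  recurrence), phase-locked to slow-wave peaks at a configurable
  phase-locking value, plus slow waves and stage-coloured background
  noise;
* artefact injection (high-amplitude transients and flat disconnection
  gaps) with ground truth.

Subject-specific traits (band-power baselines, cycle timing, spindle peak
frequency, REM-duration trend) induce the within-subject similarity and
two-cluster structure that the warping analyses are expected to recover.

Randomness: every draw descends from one root seed through
``numpy.random.SeedSequence(root, subject, night, stream)`` so that any
night is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import i0, i1
from scipy.optimize import brentq
from scipy.stats import norm

from .core import (
    BAND_NAMES,
    Hypnogram,
    NREM_STAGES,
    Recording,
    SpindleEvent,
    BandPowerSeries,
)
from .cycles import segment_cycles

__all__ = [
    "SubjectProfile",
    "GeneratedNight",
    "make_profile",
    "simulate_hypnogram",
    "simulate_bandpower",
    "simulate_raw_eeg",
    "inject_artifacts",
    "generate_night",
    "generate_cohort",
]

# per-stage mean log10 band power (µV²), rows delta..beta — chosen to respect
# the canonical orderings delta(N3) > delta(N2) > delta(REM), sigma(N2) > sigma(REM)
_DEFAULT_BASELINES: dict[str, tuple[float, ...]] = {
    "W": (1.5, 1.2, 1.9, 1.0, 1.35),
    "N1": (1.7, 1.6, 1.55, 1.1, 1.05),
    "N2": (2.2, 1.35, 1.15, 1.7, 0.9),
    "N3": (2.7, 1.7, 0.9, 1.4, 0.6),
    "REM": (1.6, 1.65, 1.55, 0.9, 1.25),
}

_CLUSTER1_SPINDLE_HZ = 13.5
_CLUSTER2_SPINDLE_HZ = 12.3  # "slower spindles", >= 1 Hz below cluster 1


@dataclass
class SubjectProfile:
    """Latent traits of one synthetic subject.

    ``band_baselines`` maps stage -> 5 mean log10 powers (delta..beta).
    ``first_cycle_scale < second_cycle_scale`` encodes the shorter first
    and longer second sleep cycle.
    """

    subject_id: str = "s01"
    cycle_mean_min: float = 98.0
    cycle_sd_min: float = 20.0
    first_cycle_scale: float = 0.94
    second_cycle_scale: float = 1.13
    late_cycle_scale: float = 0.98
    n_cycles_range: tuple[int, int] = (3, 5)
    band_baselines: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES)
    )
    delta_decline_rate: float = 0.15  # fraction of delta power lost per cycle
    sigma_surge_lead_min: float = 3.0
    sigma_surge_gain: float = 1.5
    spindle_peak_hz: float = _CLUSTER1_SPINDLE_HZ
    spindle_slow_period_s: float = 4.5
    spindle_infraslow_period_s: float = 45.0
    plv_target: float = 0.2
    noise_sd: float = 0.1  # log10-power units
    rem_duration_trend: str = "increasing"  # or "fixed" (cluster-2 trait)
    cluster: int = 1

    def __post_init__(self) -> None:
        if self.cycle_mean_min <= 0:
            raise ValueError("cycle_mean_min must be positive")
        lo, hi = self.n_cycles_range
        if not (1 <= lo <= hi <= 8):
            raise ValueError("n_cycles_range must lie within [1, 8]")
        if not 0.0 <= self.plv_target <= 1.0:
            raise ValueError("plv_target must be in [0, 1]")
        if not self.first_cycle_scale < self.second_cycle_scale:
            raise ValueError("first_cycle_scale must be < second_cycle_scale")
        if self.rem_duration_trend not in ("increasing", "fixed"):
            raise ValueError("rem_duration_trend must be 'increasing' or 'fixed'")


@dataclass
class GeneratedNight:
    """One synthetic night with its planted ground truth."""

    hypnogram: Hypnogram
    bandpower: BandPowerSeries
    recording: Recording | None = None
    events: list[SpindleEvent] = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    seed: int = 0
    subject_id: str = "s01"
    night_index: int = 0


def _sub_seed(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(keys))


def make_profile(seed: int, cluster: int = 1) -> SubjectProfile:
    """Draw a subject profile; deterministic given ``seed``.

    ``cluster`` selects the planted trait group: cluster 2 subjects have
    slower spindles (12.3 vs 13.5 Hz) and a fixed (rather than increasing)
    REM duration across cycles. All other per-subject jitter is drawn
    identically for both clusters at the same seed.
    """
    if cluster not in (1, 2):
        raise ValueError(f"cluster must be 1 or 2, got {cluster!r}")
    rng = _sub_seed(seed, 0)
    # cluster-independent subject jitter (drawn before applying traits)
    cycle_mean = 98.0 + rng.normal(0.0, 6.0)
    baselines = {
        stage: tuple(np.asarray(vals) + rng.normal(0.0, 0.05, size=5))
        for stage, vals in _DEFAULT_BASELINES.items()
    }
    decline = float(np.clip(rng.normal(0.15, 0.02), 0.08, 0.25))
    plv = float(np.clip(rng.normal(0.2, 0.05), 0.08, 0.4))
    if cluster == 1:
        spindle_hz, trend = _CLUSTER1_SPINDLE_HZ, "increasing"
    else:
        spindle_hz, trend = _CLUSTER2_SPINDLE_HZ, "fixed"
    return SubjectProfile(
        subject_id=f"s{seed:03d}",
        cycle_mean_min=cycle_mean,
        band_baselines=baselines,
        delta_decline_rate=decline,
        plv_target=plv,
        spindle_peak_hz=spindle_hz,
        rem_duration_trend=trend,
        cluster=cluster,
    )


def simulate_hypnogram(profile: SubjectProfile, seed: int) -> Hypnogram:
    """Semi-Markov stage sequence for one night.

    Each cycle unfolds as N1 -> N2 -> (N3 <-> N2) -> REM with durations
    drawn from the profile; brief awakenings overwrite N2 epochs with
    per-night probability 0.5 and geometric durations.
    """
    rng = _sub_seed(seed, 1)
    epw = 30.0
    lo, hi = profile.n_cycles_range
    n_cycles = int(rng.integers(lo, hi + 1))

    def minutes_to_epochs(m: float) -> int:
        return max(1, int(round(m * 60.0 / epw)))

    labels: list[str] = ["W"] * minutes_to_epochs(rng.uniform(2.0, 8.0))
    for c in range(n_cycles):
        if c == 0:
            scale = profile.first_cycle_scale
        elif c == 1:
            scale = profile.second_cycle_scale
        else:
            scale = profile.late_cycle_scale
        total = float(
            np.clip(rng.normal(profile.cycle_mean_min * scale, profile.cycle_sd_min), 45.0, 180.0)
        )
        if profile.rem_duration_trend == "increasing":
            rem_frac = min(0.36, 0.10 + 0.08 * c)
        else:
            rem_frac = 0.22
        rem = max(4.0, total * rem_frac)
        nrem = total - rem
        n1 = min(0.2 * nrem, 5.0 if c == 0 else float(rng.uniform(0.5, 2.0)))
        n3 = max(2.0, nrem * max(0.05, 0.45 * (1.0 - 0.28 * c)))
        n2a = max(2.0, 0.5 * (nrem - n1 - n3))
        n2b = max(2.0, nrem - n1 - n3 - n2a)
        blocks: list[tuple[str, float]] = [("N1", n1), ("N2", n2a)]
        if n3 >= 8.0 and rng.random() < 0.5:  # N3 <-> N2 alternation
            blocks += [("N3", n3 * 0.55), ("N2", 2.0), ("N3", n3 * 0.45)]
        else:
            blocks += [("N3", n3)]
        blocks += [("N2", n2b), ("REM", rem)]
        for stage, dur in blocks:
            labels.extend([stage] * minutes_to_epochs(dur))
    labels.extend(["W"] * minutes_to_epochs(rng.uniform(1.0, 4.0)))
    arr = np.asarray(labels, dtype=object)

    # brief awakenings (WASO): overwrite interior N2 epochs, never REM
    if rng.random() < 0.5:
        n2_idx = np.flatnonzero(arr == "N2")
        for _ in range(int(rng.integers(1, 4))):
            if n2_idx.size < 12:
                break
            dur_ep = int(min(rng.geometric(1.0 / 3.0), 9))  # < 5 min
            start = int(rng.choice(n2_idx[n2_idx < arr.size - dur_ep - 1]))
            arr[start : start + dur_ep] = "W"
    return Hypnogram(arr, epoch_s=epw)


def _spindle_band_split(peak_hz: float, width_hz: float = 1.0) -> tuple[float, float]:
    """Fractions of a Gaussian spindle spectral bump falling in the sigma
    (12-16 Hz) and alpha (8-12 Hz) bands."""
    f_sigma = norm.cdf((16.0 - peak_hz) / width_hz) - norm.cdf((12.0 - peak_hz) / width_hz)
    f_alpha = norm.cdf((12.0 - peak_hz) / width_hz) - norm.cdf((8.0 - peak_hz) / width_hz)
    return float(f_sigma), float(f_alpha)


def simulate_bandpower(
    hypnogram: Hypnogram,
    profile: SubjectProfile,
    seed: int,
    bin_s: float = 12.0,
    n_bins: int | None = None,
) -> BandPowerSeries:
    """Stage-conditioned log-normal band powers on a 12-s grid.

    Planted dynamics: per-stage baselines; delta multiplied by
    ``(1 - delta_decline_rate)**cycle`` in N2/N3; within-N2 sigma and delta
    ramp up together; within-N3 sigma decays while delta keeps rising
    (producing the positive-N2 / negative-N3 sigma-delta correlations);
    sigma surges by ``sigma_surge_gain`` over the ``sigma_surge_lead_min``
    minutes before each REM onset; the spindle spectral bump is split
    between sigma and alpha according to ``spindle_peak_hz``.
    """
    L = int(hypnogram.duration_s // bin_s)
    if n_bins is not None and abs(n_bins - L) > 1:
        raise ValueError(
            f"requested {n_bins} bins but hypnogram duration supports {L} bins of {bin_s} s"
        )
    if n_bins is not None:
        L = n_bins
    rng = _sub_seed(seed, 2)
    centers = (np.arange(L) + 0.5) * bin_s
    stages = hypnogram.stage_at(centers)
    logp = np.empty((5, L), dtype=float)
    for stage in set(stages.tolist()):
        sel = stages == stage
        logp[:, sel] = np.asarray(profile.band_baselines[stage])[:, None]

    i_d, i_a, i_s = BAND_NAMES.index("delta"), BAND_NAMES.index("alpha"), BAND_NAMES.index("sigma")

    # homeostatic delta decline across cycles (N2/N3 bins)
    cycles = segment_cycles(hypnogram)
    cyc_idx = np.zeros(L, dtype=int)
    for k, cyc in enumerate(cycles):
        t0 = cyc.start_epoch * hypnogram.epoch_s
        cyc_idx[centers >= t0] = k
    in_deep = np.isin(stages, ("N2", "N3"))
    logp[i_d, in_deep] += cyc_idx[in_deep] * np.log10(1.0 - profile.delta_decline_rate)

    # within-run ramps
    run_start = 0
    for i in range(1, L + 1):
        if i == L or stages[i] != stages[run_start]:
            n = i - run_start
            stage = stages[run_start]
            if n >= 2 and stage in ("N2", "N3"):
                ramp = np.linspace(-1.0, 1.0, n)
                if stage == "N2":
                    logp[i_s, run_start:i] += 0.15 * ramp
                    logp[i_d, run_start:i] += 0.12 * ramp
                else:  # N3: sigma decays while delta keeps rising
                    logp[i_s, run_start:i] += np.linspace(0.05, -0.30, n)
                    logp[i_d, run_start:i] += np.linspace(-0.10, 0.15, n)
            run_start = i

    # spindle-frequency trait: redistribute the spindle bump across sigma/alpha;
    # slow spindles (~12 Hz) straddle the band edge and leak strongly into alpha
    f_sig, f_alp = _spindle_band_split(profile.spindle_peak_hz)
    logp[i_s, in_deep] += np.log10(0.02 + 0.98 * f_sig)
    logp[i_a, in_deep] += np.log10(1.0 + 12.0 * f_alp)

    # pre-REM sigma surge on NREM bins
    lead = max(1, int(round(profile.sigma_surge_lead_min * 60.0 / bin_s)))
    gain = np.log10(profile.sigma_surge_gain)
    is_rem = stages == "REM"
    onsets = np.flatnonzero(is_rem & ~np.r_[False, is_rem[:-1]])
    nrem_bin = np.isin(stages, NREM_STAGES)
    for t0 in onsets:
        a = max(0, t0 - lead)
        w = (np.arange(a, t0) - (t0 - lead) + 1) / lead
        sel = nrem_bin[a:t0]
        logp[i_s, a:t0][sel] += gain * np.clip(w[sel], 0.0, 1.0)

    logp += rng.normal(0.0, profile.noise_sd, size=(5, L))
    return BandPowerSeries(10.0**logp, bin_s=bin_s, start_time=hypnogram.start_time)


def _vonmises_kappa(plv: float) -> float:
    """Concentration kappa with mean resultant length ``plv``."""
    if plv <= 1e-6:
        return 0.0
    if plv >= 0.999:
        return 500.0
    return float(brentq(lambda k: i1(k) / i0(k) - plv, 1e-6, 500.0))


def simulate_raw_eeg(
    hypnogram: Hypnogram,
    profile: SubjectProfile,
    seed: int,
    fs: float = 207.0,
    spindle_amp_factor: float = 6.0,
) -> tuple[Recording, list[SpindleEvent], dict]:
    """Raw 207-Hz EEG with planted spindles and slow waves.

    The signal is stage-coloured background noise plus a 0.85 Hz slow-wave
    carrier in N2/N3 (boosted into discrete high-amplitude slow waves),
    plus spindle bursts at ``spindle_peak_hz`` planted in trains gated by
    the infra-slow rhythm. Spindle onset phases relative to the slow-wave
    carrier are von Mises draws concentrated at the slow-wave peak with
    mean resultant length ``plv_target``.

    ``spindle_amp_factor`` is the target ratio of spindle envelope peak to
    the mean 11-16 Hz envelope of the final N2/N3 signal; the planted
    amplitude is solved self-consistently so the ratio holds after the
    spindles themselves inflate that mean.

    Returns ``(recording, spindle_events, truth)`` where ``truth`` carries
    planted spindle onset phases, slow-wave times and the carrier
    frequency.
    """
    rng = _sub_seed(seed, 3)
    n = int(round(hypnogram.duration_s * fs))
    t = np.arange(n) / fs
    stages = hypnogram.stage_at(t)
    in_deep = np.isin(stages, ("N2", "N3"))

    # stage-coloured background noise (lowpass to ~35 Hz)
    sos = signal.butter(2, 35.0 / (fs / 2.0), btype="low", output="sos")
    bg = signal.sosfiltfilt(sos, rng.standard_normal(n))
    bg /= bg.std()
    amp = np.full(n, 9.0)
    for stage, a in (("W", 10.0), ("N1", 9.0), ("N2", 10.0), ("N3", 14.0), ("REM", 8.0)):
        amp[stages == stage] = a
    sig = bg * amp

    # slow-wave carrier, peak at phase 0
    f_sw = 0.85
    phase = 2.0 * np.pi * f_sw * t
    carrier_amp = np.zeros(n)
    carrier_amp[stages == "N2"] = 7.0
    carrier_amp[stages == "N3"] = 18.0
    sig += carrier_amp * np.cos(phase)

    # discrete planted slow waves: boosted carrier cycles in N3 (some N2)
    slow_truth: list[tuple[float, float, float]] = []
    boost = np.zeros(n)
    for stage_sel, rate_s in (("N3", 5.0), ("N2", 12.0)):
        for s0, s1 in _sample_runs(stages == stage_sel):
            tc = t[s0] + rng.uniform(0.0, rate_s)
            while tc < t[s1 - 1] - 1.0:
                a_evt = float(rng.lognormal(np.log(45.0), 0.2))
                half = 0.8
                i0_, i1_ = int((tc - half) * fs), int((tc + half) * fs)
                if i0_ >= s0 and i1_ < s1:
                    win = signal.windows.tukey(i1_ - i0_, 0.5)
                    boost[i0_:i1_] += a_evt * win
                    seg_phase = phase[i0_:i1_]
                    trough_rel = np.argmin(np.cos(seg_phase))
                    peak_rel = np.argmax(np.cos(seg_phase))
                    slow_truth.append(
                        (t[i0_ + trough_rel], t[i0_ + peak_rel], a_evt)
                    )
                tc += rng.uniform(0.7 * rate_s, 1.3 * rate_s)
    sig += boost * np.cos(phase)

    # spindle placement: infra-slow-gated trains inside N2/N3 runs
    kappa = _vonmises_kappa(profile.plv_target)
    T_inf = profile.spindle_infraslow_period_s
    placements: list[tuple[float, float, float, float]] = []  # onset, dur, rel_amp, freq
    phases: list[float] = []
    for s0, s1 in _sample_runs(in_deep):
        tcur = t[s0] + rng.uniform(0.0, 2.0)
        t_end = t[s1 - 1]
        while tcur < t_end - 2.0:
            frac = (tcur % T_inf) / T_inf
            if min(frac, 1.0 - frac) < 0.125:  # top quarter of infra-slow cycle
                theta = float(rng.vonmises(0.0, kappa)) if kappa > 0 else float(
                    rng.uniform(-np.pi, np.pi)
                )
                # shift onset to the nearest time at carrier phase theta
                dphi = np.angle(np.exp(1j * (theta - 2.0 * np.pi * f_sw * tcur)))
                onset = tcur + dphi / (2.0 * np.pi * f_sw)
                dur = float(rng.uniform(0.9, 1.4))
                if t[s0] < onset and onset + dur < t_end:
                    placements.append(
                        (
                            onset,
                            dur,
                            float(rng.uniform(0.92, 1.08)),
                            profile.spindle_peak_hz + float(rng.normal(0.0, 0.2)),
                        )
                    )
                    phases.append(float(np.angle(np.exp(1j * 2.0 * np.pi * f_sw * onset))))
                tcur += float(np.clip(rng.normal(profile.spindle_slow_period_s, 0.6), 2.5, None))
            else:
                tcur += 0.25

    # self-consistent spindle amplitude calibration (see module docstring)
    sos_sp = signal.butter(4, [11.0 / (fs / 2.0), 16.0 / (fs / 2.0)], btype="band", output="sos")
    env_bg = np.abs(signal.hilbert(signal.sosfiltfilt(sos_sp, sig)))
    deep_time = max(in_deep.sum() / fs, 1.0)
    m_bg = float(env_bg[in_deep].mean()) if in_deep.any() else float(env_bg.mean())
    eps = 0.875  # mean of the Tukey(0.25) spindle envelope
    c = eps * sum(d * u for _, d, u, _ in placements) / deep_time
    f = spindle_amp_factor
    A = f * m_bg / max(1.0 - f * c, 0.2)

    events: list[SpindleEvent] = []
    for onset, dur, u, freq in placements:
        i0_, i1_ = int(onset * fs), int((onset + dur) * fs)
        win = signal.windows.tukey(i1_ - i0_, 0.25)
        tt = t[i0_:i1_] - onset
        sig[i0_:i1_] += A * u * win * np.sin(2.0 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
        events.append(SpindleEvent(onset, onset + dur, peak_amplitude=A * u, mean_freq=freq))
    events.sort(key=lambda e: e.onset_s)

    rec = Recording(sig, fs=fs, start_time=hypnogram.start_time)
    truth = {
        "spindle_phases": np.asarray(phases),
        "slow_waves": slow_truth,
        "f_sw": f_sw,
        "spindle_amplitude": A,
        "background_env_mean": m_bg,
    }
    return rec, events, truth


def _sample_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean array as (start, end) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


def inject_artifacts(recording: Recording, rate: float, seed: int) -> Recording:
    """Insert high-amplitude transients and flat disconnection gaps.

    ``rate`` is the expected number of artefact intervals per hour
    (70 % transients, 30 % gaps). Ground-truth intervals are appended to
    ``artifact_truth`` on the returned copy; the input is untouched.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    out = recording.copy()
    if rate == 0:
        return out
    rng = _sub_seed(seed, 4)
    hours = recording.duration_s / 3600.0
    n_events = int(rng.poisson(rate * hours))
    sd = float(np.std(recording.samples))
    fs = recording.fs
    for _ in range(n_events):
        kind = "transient" if rng.random() < 0.7 else "gap"
        dur = float(rng.uniform(0.3, 1.5)) if kind == "transient" else float(rng.uniform(2.0, 8.0))
        onset = float(rng.uniform(0.0, recording.duration_s - dur))
        a, b = int(onset * fs), int((onset + dur) * fs)
        if kind == "transient":
            burst = rng.standard_normal(b - a) * 10.0 * sd
            # guarantee the advertised >5x background-SD excursion
            burst[np.argmax(np.abs(burst))] = np.sign(burst[np.argmax(np.abs(burst))]) * max(
                np.abs(burst).max(), 6.0 * sd
            )
            out.samples[a:b] += burst
        else:
            out.samples[a:b] = 0.0
        out.artifact_truth.append((onset, onset + dur, kind))
    out.artifact_truth.sort()
    return out


def generate_night(
    profile: SubjectProfile,
    seed: int,
    with_raw: bool = False,
    subject_id: str | None = None,
    night_index: int = 0,
) -> GeneratedNight:
    """Convenience wrapper producing one fully assembled night."""
    hyp = simulate_hypnogram(profile, seed)
    bp = simulate_bandpower(hyp, profile, seed)
    rec, events, truth = (None, [], {})
    if with_raw:
        rec, events, truth = simulate_raw_eeg(hyp, profile, seed)
    return GeneratedNight(
        hypnogram=hyp,
        bandpower=bp,
        recording=rec,
        events=events,
        truth=truth,
        seed=seed,
        subject_id=subject_id or profile.subject_id,
        night_index=night_index,
    )


def generate_cohort(
    n_subjects: int = 8,
    nights_per_subject: int = 10,
    seed: int = 0,
    clusters: list[int] | None = None,
    with_raw: bool = False,
) -> tuple[list[SubjectProfile], list[GeneratedNight]]:
    """Generate a multi-subject cohort.

    By default the last quarter of subjects (at least one, e.g. 2 of 8,
    mirroring the study's 6-vs-2 split) belong to trait cluster 2.
    """
    if clusters is None:
        n2 = max(1, n_subjects // 4)
        clusters = [1] * (n_subjects - n2) + [2] * n2
    if len(clusters) != n_subjects:
        raise ValueError("clusters must have one entry per subject")
    root = np.random.SeedSequence(seed)
    profiles: list[SubjectProfile] = []
    nights: list[GeneratedNight] = []
    for s_idx in range(n_subjects):
        s_seed = int(np.random.SeedSequence([seed, s_idx]).generate_state(1)[0] % (2**31))
        profile = make_profile(s_seed, clusters[s_idx])
        profile.subject_id = f"s{s_idx + 1:02d}"
        profiles.append(profile)
        for n_idx in range(nights_per_subject):
            night_seed = int(
                np.random.SeedSequence([seed, s_idx, n_idx]).generate_state(1)[0] % (2**31)
            )
            nights.append(
                generate_night(
                    profile,
                    night_seed,
                    with_raw=with_raw,
                    subject_id=profile.subject_id,
                    night_index=n_idx,
                )
            )
    del root
    return profiles, nights
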