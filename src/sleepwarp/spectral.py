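"""Pre-processing and multitaper band-power estimation.

The spectral representation used throughout the package is a 5xL matrix of
band powers (delta 1-4, theta 4-8, alpha 8-12, sigma 12-16, beta 16-30 Hz)
computed per non-overlapping 12-s bin with a DPSS multitaper estimate
(7 tapers, time-bandwidth product NW = 4, so K = 2*NW - 1).

Artefact handling is mean-relative masking: 1-s windows whose absolute
voltage or line-length (mean |first difference| x fs, µV/s) exceeds the
thresholds are marked unusable, as are flat-lined (disconnection) windows.
Sample values are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

from .core import BAND_EDGES, BAND_NAMES, BandPowerSeries, Recording

__all__ = [
    "mask_artifacts",
    "calibrate_linelength_threshold",
    "multitaper_bandpower",
    "zscore_bands",
    "sigma_envelope_spectrum",
    "EnvelopeSpectrum",
]


def _window_linelength(x: np.ndarray, fs: float, win_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (max |voltage|, line-length in µV/s) over non-overlapping
    windows of ``win_s`` seconds; the ragged tail forms a final window."""
    w = max(2, int(round(win_s * fs)))
    n = x.size
    edges = list(range(0, n, w))
    vmax = np.empty(len(edges))
    ll = np.empty(len(edges))
    absdiff = np.abs(np.diff(x, prepend=x[0]))
    for k, a in enumerate(edges):
        b = min(a + w, n)
        vmax[k] = np.max(np.abs(x[a:b]))
        ll[k] = absdiff[a:b].mean() * fs
    return vmax, ll


def calibrate_linelength_threshold(recording: Recording, quantile: float = 0.999) -> float:
    """Line-length threshold as a high quantile of windowed line-length on a
    (presumed clean) recording."""
    _, ll = _window_linelength(np.atleast_1d(recording.samples), recording.fs, 1.0)
    return float(np.quantile(ll, quantile))


def mask_artifacts(
    recording: Recording,
    voltage_thresh: float = 350.0,
    linelength_thresh: float | None = None,
    window_s: float = 1.0,
) -> Recording:
    """Mask artefactual windows; never alters sample values.

    A 1-s window is masked when its peak |voltage| exceeds
    ``voltage_thresh`` (µV, default the device's 350 µV dynamic range),
    when its line-length exceeds ``linelength_thresh`` (µV/s; default 8x
    the recording's median windowed line-length), or when it is flat-lined
    (line-length below 1 % of the median — a disconnection).
    """
    x = np.atleast_1d(recording.samples)
    if x.size == 0:
        raise ValueError("empty recording")
    if voltage_thresh <= 0 or (linelength_thresh is not None and linelength_thresh <= 0):
        raise ValueError("thresholds must be positive")
    vmax, ll = _window_linelength(x, recording.fs, window_s)
    med_ll = float(np.median(ll))
    if linelength_thresh is None:
        linelength_thresh = 8.0 * med_ll
    bad = (vmax > voltage_thresh) | (ll > linelength_thresh) | (ll < 0.01 * med_ll)
    out = recording.copy()
    w = max(2, int(round(window_s * recording.fs)))
    for k in np.flatnonzero(bad):
        out.mask[k * w : min((k + 1) * w, x.size)] = False
    return out


def multitaper_bandpower(
    recording: Recording,
    bin_s: float = 12.0,
    n_tapers: int = 7,
    nw: float = 4.0,
    band_edges: tuple[tuple[float, float], ...] = BAND_EDGES,
) -> BandPowerSeries:
    """DPSS multitaper band powers per non-overlapping ``bin_s`` bin.

    Per bin, the one-sided PSD is averaged over ``n_tapers`` Slepian
    tapers (time-bandwidth product ``nw``; the default pairing 7 tapers =
    2*NW - 1 with NW = 4) and integrated (trapezoid) over each band's
    frequency range. Bins with more than 50 % masked samples are flagged
    invalid but still estimated.
    """
    if n_tapers > 2 * nw - 1:
        raise ValueError(
            f"n_tapers={n_tapers} exceeds 2*NW-1={int(2 * nw - 1)} for NW={nw}; "
            "increase nw or reduce n_tapers to keep taper leakage bounded"
        )
    fs = recording.fs
    if fs <= 2 * max(hi for _, hi in band_edges):
        raise ValueError("sampling rate too low for the requested bands")
    nper = int(round(bin_s * fs))
    x = np.atleast_1d(recording.samples)
    if x.size < nper:
        raise ValueError("recording shorter than one bin")
    n_bins = x.size // nper
    tapers = dpss(nper, nw, Kmax=n_tapers)  # (K, nper), unit-energy
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    # one-sided PSD scale: |X|^2 / fs, doubled except DC/Nyquist
    scale = np.full(freqs.size, 2.0 / fs)
    scale[0] = 1.0 / fs
    if nper % 2 == 0:
        scale[-1] = 1.0 / fs
    band_rows = []
    sel = [(freqs >= lo) & (freqs < hi) for lo, hi in band_edges]
    values = np.empty((len(band_edges), n_bins))
    valid = np.empty(n_bins, dtype=bool)
    for b in range(n_bins):
        seg = x[b * nper : (b + 1) * nper]
        seg = seg - seg.mean()
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        psd = (np.abs(spec) ** 2).mean(axis=0) * scale
        for i, m in enumerate(sel):
            values[i, b] = np.trapezoid(psd[m], freqs[m]) if m.sum() > 1 else psd[m].sum()
        valid[b] = recording.mask[b * nper : (b + 1) * nper].mean() > 0.5
    del band_rows
    return BandPowerSeries(
        values, bin_s=bin_s, band_edges=band_edges, valid=valid, start_time=recording.start_time
    )


def zscore_bands(
    series: BandPowerSeries | list[BandPowerSeries],
    scope: str = "night",
) -> BandPowerSeries | list[BandPowerSeries]:
    """Z-score each band over valid bins.

    ``scope='night'`` normalises one series over its own valid bins;
    ``scope='subject'`` takes a list of series, pools their valid bins for
    the mean/SD, and returns a matching list. Invalid bins pass through
    untouched (their stored values are irrelevant downstream).
    """
    if scope not in ("night", "subject"):
        raise ValueError("scope must be 'night' or 'subject'")
    many = isinstance(series, (list, tuple))
    if scope == "subject" and not many:
        raise ValueError("scope='subject' requires a list of series")
    items = list(series) if many else [series]
    pooled = np.concatenate([s.values[:, s.valid] for s in items], axis=1)
    if pooled.shape[1] < 2:
        raise ValueError("need at least 2 valid bins to z-score")
    outputs = []
    for s in items:
        out = s.copy()
        if scope == "night":
            ref = s.values[:, s.valid]
            if ref.shape[1] < 2:
                raise ValueError("need at least 2 valid bins to z-score")
        else:
            ref = pooled
        mu = ref.mean(axis=1)
        sd = ref.std(axis=1)
        for i, name in enumerate(BAND_NAMES):
            if sd[i] == 0:
                raise ValueError(f"band '{name}' has zero variance; cannot z-score")
        out.values[:, out.valid] = (s.values[:, s.valid] - mu[:, None]) / sd[:, None]
        outputs.append(out)
    return outputs if many else outputs[0]


@dataclass(frozen=True)
class EnvelopeSpectrum:
    """Low-frequency (<1 Hz) spectrum of the sigma-band envelope."""

    freqs: np.ndarray
    power: np.ndarray
    band_source: str = "sigma"

    def peak_freq(self, fmin: float, fmax: float) -> float:
        """Frequency of maximal power within [fmin, fmax]."""
        m = (self.freqs >= fmin) & (self.freqs <= fmax)
        if not m.any():
            raise ValueError("no spectral bins in requested range")
        return float(self.freqs[m][np.argmax(self.power[m])])


def sigma_envelope_spectrum(
    recording: Recording,
    n2n3_mask: np.ndarray,
    env_fs: float = 2.0,
    nperseg_s: float = 512.0,
    mode: str = "analytic",
) -> EnvelopeSpectrum:
    """Spectrum of the sigma-band envelope, restricted to < 1 Hz.

    The signal is band-passed 11-16 Hz; the envelope is the magnitude of
    the analytic signal (``mode='analytic'``) or its square
    (``mode='power'``). The envelope is decimated to ``env_fs`` and a
    Welch spectrum is averaged over contiguous N2/N3 runs, resolving both
    the ~4-5 s (slow) and ~40-50 s (infra-slow) spindle periodicities.
    """
    if mode not in ("analytic", "power"):
        raise ValueError("mode must be 'analytic' or 'power'")
    n2n3_mask = np.asarray(n2n3_mask, dtype=bool)
    fs = recording.fs
    if n2n3_mask.sum() / fs < 300.0:
        raise ValueError("need at least 5 min of N2/N3 signal")
    sos = signal.butter(4, [11.0 / (fs / 2.0), 16.0 / (fs / 2.0)], btype="band", output="sos")
    env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, np.atleast_1d(recording.samples))))
    if mode == "power":
        env = env**2
    step = max(1, int(round(fs / env_fs)))
    # anti-alias smooth then decimate
    env_s = signal.sosfiltfilt(
        signal.butter(2, 0.9 * env_fs / 2.0 / (fs / 2.0), btype="low", output="sos"), env
    )[::step]
    mask_s = n2n3_mask[::step]
    fs_env = fs / step

    nper = int(nperseg_s * fs_env)
    spectra = []
    from .synthgen import _sample_runs  # contiguous-run helper

    for a, b in _sample_runs(mask_s):
        if (b - a) / fs_env < 120.0:
            continue
        seg = env_s[a:b] - env_s[a:b].mean()
        f, p = signal.welch(seg, fs=fs_env, nperseg=min(nper, seg.size), detrend="linear")
        spectra.append((f, p, b - a))
    if not spectra:
        raise ValueError("no contiguous N2/N3 run of at least 2 min")
    # average on the finest common grid, weighted by run length
    f_ref = max(spectra, key=lambda s: s[0].size)[0]
    acc = np.zeros_like(f_ref)
    wsum = 0.0
    for f, p, w in spectra:
        acc += np.interp(f_ref, f, p) * w
        wsum += w
    keep = (f_ref > 0) & (f_ref < 1.0)
    return EnvelopeSpectrum(freqs=f_ref[keep], power=acc[keep] / wsum, band_source="sigma")
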