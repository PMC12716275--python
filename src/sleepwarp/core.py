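"""Core containers for longitudinal sleep-EEG analysis.

The package represents one night of sleep at three levels:

* :class:`Recording` — raw (sub-scalp) EEG samples with a per-sample
  usability mask;
* :class:`Hypnogram` — visually scored sleep stages on a 30-s epoch grid;
* :class:`BandPowerSeries` — the 5xL matrix of band powers
  (delta, theta, alpha, sigma, beta) on a 12-s grid that every downstream
  analysis (warping, forecasting) consumes.

Discrete oscillatory events (spindles, slow waves) and phase-locking
summaries also live here so that detector modules and the synthetic
generator share one vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: canonical stage labels, in hypnogram order
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES: tuple[str, ...] = ("N1", "N2", "N3", "REM")
NREM_STAGES: tuple[str, ...] = ("N1", "N2", "N3")

#: band names and integration edges in Hz: delta, theta, alpha, sigma, beta
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "sigma", "beta")
BAND_EDGES: tuple[tuple[float, float], ...] = (
    (1.0, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 16.0),
    (16.0, 30.0),
)

#: default band-power bin and hypnogram epoch lengths, seconds
DEFAULT_BIN_S = 12.0
DEFAULT_EPOCH_S = 30.0


class QCError(ValueError):
    """A night failed a quality-control rule.

    Parameters
    ----------
    reason
        Machine-readable rejection reason, e.g. ``"min-cycles"`` or
        ``"disconnection"``.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or f"night rejected: {reason}")


@dataclass
class Recording:
    """Single-channel raw EEG for one night.

    Attributes
    ----------
    samples : ndarray, µV
        The voltage trace.
    fs : float, Hz
        Sampling rate (nominally 207 Hz for the sub-scalp device).
    channels : list of str
        Channel labels; analyses operate on the first channel only.
    mask : bool ndarray
        Per-sample usability flag, ``True`` = usable. Same length as
        ``samples``.
    start_time : float
        Clock time of the first sample, seconds since midnight.
    artifact_truth : list of (onset_s, offset_s, kind)
        Ground-truth artefact intervals, populated by the synthetic
        generator's artefact injector; empty for real data.
    """

    samples: np.ndarray
    fs: float = 207.0
    channels: Sequence[str] = ("sqEEG",)
    mask: np.ndarray | None = None
    start_time: float = 23.0 * 3600.0
    artifact_truth: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.mask is None:
            self.mask = np.ones(self.samples.shape[-1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape[-1] != self.samples.shape[-1]:
                raise ValueError("mask length must equal samples length")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[-1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            mask=self.mask.copy(),
            artifact_truth=list(self.artifact_truth),
        )


@dataclass
class Hypnogram:
    """Visually scored stages on a fixed epoch grid (default 30 s)."""

    labels: np.ndarray
    epoch_s: float = DEFAULT_EPOCH_S
    start_time: float = 23.0 * 3600.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size == 0:
            raise ValueError("hypnogram labels must be non-empty")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        bad = set(self.labels.tolist()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}; allowed: {STAGES}")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def stage_at(self, t_s: np.ndarray | float) -> np.ndarray:
        """Stage label at time(s) ``t_s`` seconds from night start."""
        idx = np.clip(
            (np.asarray(t_s, dtype=float) // self.epoch_s).astype(int),
            0,
            self.n_epochs - 1,
        )
        return self.labels[idx]

    def sample_mask(self, fs: float, n_samples: int, stages: Sequence[str]) -> np.ndarray:
        """Boolean per-sample mask of membership in ``stages``."""
        t = np.arange(n_samples) / fs
        lab = self.stage_at(t)
        return np.isin(lab, list(stages))

    def runs(self) -> list[tuple[str, int, int]]:
        """Maximal constant-stage runs as ``(stage, start_epoch, end_epoch)``,
        end exclusive."""
        out: list[tuple[str, int, int]] = []
        start = 0
        lab = self.labels
        for i in range(1, lab.size + 1):
            if i == lab.size or lab[i] != lab[start]:
                out.append((str(lab[start]), start, i))
                start = i
        return out


@dataclass
class BandPowerSeries:
    """5xL matrix of band powers on a regular bin grid.

    Rows follow :data:`BAND_NAMES` (delta, theta, alpha, sigma, beta);
    values are linear power in µV². ``valid`` marks bins that survive the
    artefact mask (>50 % usable samples).
    """

    values: np.ndarray
    bin_s: float = DEFAULT_BIN_S
    band_edges: tuple[tuple[float, float], ...] = BAND_EDGES
    valid: np.ndarray | None = None
    start_time: float = 23.0 * 3600.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(BAND_NAMES):
            raise ValueError("values must be a 5 x L matrix (delta..beta rows)")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if self.valid is None:
            self.valid = np.ones(self.values.shape[1], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != self.values.shape[1]:
                raise ValueError("valid length must equal number of bins")

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_s

    def times(self) -> np.ndarray:
        """Bin-center times in seconds from night start."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_s

    def band(self, name: str) -> np.ndarray:
        return self.values[BAND_NAMES.index(name)]

    def copy(self) -> "BandPowerSeries":
        return replace(self, values=self.values.copy(), valid=self.valid.copy())


@dataclass(frozen=True)
class SpindleEvent:
    """One sleep spindle: an 11–16 Hz burst of 0.5–2.5 s in N2/N3."""

    onset_s: float
    offset_s: float
    peak_amplitude: float = np.nan
    mean_freq: float = np.nan

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("spindle onset must precede offset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class SlowWaveEvent:
    """One slow wave (0.5–4 Hz), located by its negative trough and the
    following positive peak of the band-passed trace."""

    trough_s: float
    peak_s: float
    peak_to_peak: float = np.nan


@dataclass(frozen=True)
class PhaseLockingResult:
    """Circular concentration of event phases.

    ``plv`` is the modulus of the mean unit phasor (1 = perfect locking,
    0 = uniform); ``preferred_phase`` its argument in radians.
    """

    plv: float
    preferred_phase: float
    n_events: int
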