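"""NREM-REM cycle segmentation and conventional ("static") sleep statistics.

A sleep cycle is one NREM period followed by its REM period; healthy nights
contain three to five cycles of roughly 90–100 min, with the first cycle
typically shorter and the second longer. The segmentation rules here follow
common sleep-scoring practice since no standard is universal:

* a NREM period must last >= ``min_nrem_min`` (default 15 min); shorter
  NREM intercalations are absorbed into the surrounding cycle;
* wake (W) interruptions shorter than ``max_interrupt_min`` (default 5 min)
  do not break a period;
* a terminal cycle may lack REM if at least ``min_nrem_min`` of NREM
  remains at the end of the night.

All thresholds are keyword-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Hypnogram, NREM_STAGES, SLEEP_STAGES


@dataclass(frozen=True)
class SleepCycle:
    """One NREM-REM cycle in epoch coordinates (end exclusive)."""

    start_epoch: int
    rem_start_epoch: int | None
    end_epoch: int

    def duration_min(self, epoch_s: float = 30.0) -> float:
        return (self.end_epoch - self.start_epoch) * epoch_s / 60.0

    def nrem_duration_min(self, epoch_s: float = 30.0) -> float:
        end = self.rem_start_epoch if self.rem_start_epoch is not None else self.end_epoch
        return (end - self.start_epoch) * epoch_s / 60.0

    def rem_duration_min(self, epoch_s: float = 30.0) -> float:
        if self.rem_start_epoch is None:
            return 0.0
        return (self.end_epoch - self.rem_start_epoch) * epoch_s / 60.0


def _collapse(labels: np.ndarray) -> np.ndarray:
    """Map stage labels to {'W', 'N', 'R'}."""
    out = np.empty(labels.size, dtype="U1")
    for i, lab in enumerate(labels):
        if lab == "REM":
            out[i] = "R"
        elif lab in NREM_STAGES:
            out[i] = "N"
        else:
            out[i] = "W"
    return out


def _runs(seq: np.ndarray) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, seq.size + 1):
        if i == seq.size or seq[i] != seq[start]:
            out.append((str(seq[start]), start, i))
            start = i
    return out


def segment_cycles(
    hypnogram: Hypnogram,
    min_nrem_min: float = 15.0,
    max_interrupt_min: float = 5.0,
) -> list[SleepCycle]:
    """Segment a scored night into NREM-REM cycles.

    Returns an empty list for a night with no sleep. Cycle boundaries sit
    at NREM onsets; each cycle covers its NREM period and the following
    REM period (if any).
    """
    epw = hypnogram.epoch_s
    collapsed = _collapse(hypnogram.labels)
    tol = int(round(max_interrupt_min * 60 / epw))

    # absorb short W runs into the surrounding sleep context
    runs = _runs(collapsed)
    filled = collapsed.copy()
    for kind, a, b in runs:
        if kind == "W" and (b - a) < tol and a > 0 and b < collapsed.size:
            filled[a:b] = filled[a - 1]
    runs = _runs(filled)

    # drop leading/trailing wake
    sleep_idx = np.flatnonzero(filled != "W")
    if sleep_idx.size == 0:
        return []
    onset, last = int(sleep_idx[0]), int(sleep_idx[-1]) + 1

    min_nrem_ep = int(round(min_nrem_min * 60 / epw))
    cycles: list[SleepCycle] = []
    i = onset
    cur_start: int | None = None
    rem_start: int | None = None
    while i < last:
        kind = filled[i]
        j = i
        while j < last and filled[j] == kind:
            j += 1
        if kind == "N":
            if cur_start is None:
                cur_start = i
            elif rem_start is not None:
                # NREM after REM: close current cycle at this NREM onset
                cycles.append(SleepCycle(cur_start, rem_start, i))
                cur_start, rem_start = i, None
        elif kind == "R":
            if cur_start is None:
                cur_start = i  # sleep-onset REM: cycle with empty NREM period
            rem_start = rem_start if rem_start is not None else i
        i = j
    if cur_start is not None:
        if rem_start is not None:
            cycles.append(SleepCycle(cur_start, rem_start, last))
        elif (last - cur_start) >= min_nrem_ep:
            cycles.append(SleepCycle(cur_start, None, last))
        elif cycles:
            prev = cycles.pop()
            cycles.append(SleepCycle(prev.start_epoch, prev.rem_start_epoch, last))

    # merge cycles whose NREM period is too short into their predecessor
    merged: list[SleepCycle] = []
    for cyc in cycles:
        nrem_ep = (cyc.rem_start_epoch if cyc.rem_start_epoch is not None else cyc.end_epoch) - cyc.start_epoch
        if merged and nrem_ep < min_nrem_ep:
            prev = merged.pop()
            merged.append(
                SleepCycle(
                    prev.start_epoch,
                    prev.rem_start_epoch if prev.rem_start_epoch is not None else cyc.rem_start_epoch,
                    cyc.end_epoch,
                )
            )
        else:
            merged.append(cyc)
    return merged


@dataclass(frozen=True)
class StaticStats:
    """Whole-night aggregate statistics over [sleep onset, final awakening]."""

    total_sleep_min: float
    stage_pct: dict[str, float]  # % of total sleep time per sleep stage
    waso_min: float
    n_cycles: int
    cycle_durations_min: tuple[float, ...]
    rem_pct: float


def static_stats(hypnogram: Hypnogram) -> StaticStats:
    """Conventional sleep statistics for one scored night."""
    epw = hypnogram.epoch_s
    labels = hypnogram.labels
    sleep_idx = np.flatnonzero(np.isin(labels, list(SLEEP_STAGES)))
    if sleep_idx.size == 0:
        return StaticStats(0.0, {s: 0.0 for s in SLEEP_STAGES}, 0.0, 0, (), 0.0)
    onset, last = int(sleep_idx[0]), int(sleep_idx[-1]) + 1
    inside = labels[onset:last]
    minutes = epw / 60.0
    tst = float(np.isin(inside, list(SLEEP_STAGES)).sum() * minutes)
    waso = float((inside == "W").sum() * minutes)
    pct = {s: float((inside == s).sum() * minutes) / tst * 100.0 for s in SLEEP_STAGES}
    cycles = segment_cycles(hypnogram)
    durations = tuple(c.duration_min(epw) for c in cycles)
    return StaticStats(
        total_sleep_min=tst,
        stage_pct=pct,
        waso_min=waso,
        n_cycles=len(cycles),
        cycle_durations_min=durations,
        rem_pct=pct["REM"],
    )
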