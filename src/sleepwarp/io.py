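"""Readers and writers for the package's text interchange formats.

Hypnograms, band powers, event lists and dissimilarity matrices travel as
TSV; ground truth and model outputs as JSON; dendrograms as Newick. Raw
EEG is read from EDF through MNE when available; EDF *export* additionally
requires the ``edfio`` package and raises a clear error otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BAND_NAMES, BandPowerSeries, Hypnogram, Recording


def _clock(start_time: float, offset_s: float) -> str:
    s = int(start_time + offset_s) % 86400
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def write_hypnogram_tsv(hyp: Hypnogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "clock_time": [_clock(hyp.start_time, i * hyp.epoch_s) for i in range(hyp.n_epochs)],
            "stage": hyp.labels,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram_tsv(path: str | Path, epoch_s: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    hms = df["clock_time"].iloc[0].split(":")
    start = int(hms[0]) * 3600 + int(hms[1]) * 60 + int(hms[2])
    return Hypnogram(df["stage"].to_numpy(dtype=object), epoch_s=epoch_s, start_time=float(start))


def write_bandpower_tsv(bp: BandPowerSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": bp.times()})
    for i, name in enumerate(BAND_NAMES):
        df[name] = bp.values[i]
    df["valid"] = bp.valid.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bandpower_tsv(path: str | Path) -> BandPowerSeries:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    bin_s = float(t[1] - t[0]) if t.size > 1 else 12.0
    values = np.vstack([df[name].to_numpy() for name in BAND_NAMES])
    valid = df["valid"].to_numpy().astype(bool) if "valid" in df else None
    return BandPowerSeries(values, bin_s=bin_s, valid=valid)


def write_events_tsv(events: list, night_id: str, path: str | Path, kind: str = "spindle") -> None:
    rows = []
    for e in events:
        if hasattr(e, "onset_s"):
            rows.append((night_id, e.onset_s, e.offset_s, kind, e.peak_amplitude))
        else:  # slow waves: trough/peak
            rows.append((night_id, e.trough_s, e.peak_s, "slow_wave", e.peak_to_peak))
    pd.DataFrame(
        rows, columns=["night_id", "onset_s", "offset_s", "type", "amplitude"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def read_recording_edf(path: str | Path, channel: int = 0) -> Recording:
    """Load one channel of an EDF file as a :class:`Recording` (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[channel] * 1e6  # volts -> µV
    meas = raw.info.get("meas_date")
    start = (
        meas.hour * 3600 + meas.minute * 60 + meas.second if meas is not None else 0.0
    )
    return Recording(data, fs=float(raw.info["sfreq"]), channels=[raw.ch_names[channel]], start_time=start)


def write_recording_edf(recording: Recording, path: str | Path) -> None:
    """Export a recording to EDF (requires MNE with the ``edfio`` backend)."""
    try:
        import mne

        info = mne.create_info([str(c) for c in recording.channels[:1]], recording.fs, "eeg")
        raw = mne.io.RawArray(recording.samples[None, :] * 1e-6, info, verbose="error")
        raw.export(str(path), fmt="edf", overwrite=True, verbose="error")
    except Exception as err:  # pragma: no cover - depends on optional backend
        raise RuntimeError(
            "EDF export needs MNE with the 'edfio' backend installed; "
            "use the TSV writers for text-only persistence"
        ) from err
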