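"""Reading and writing recordings, epochs and feature tables.

The native on-disk format is plain CSV: one samples file per subject
(column ``time_s`` plus one column per channel) with an events sidecar
(``stage,start_sample,end_sample``).  EDF recordings with stage
annotations can be read through MNE when it is installed (the ``edf``
extra); EDF writing is not provided.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import StageEpochSet
from .simulate import Recording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "read_recording_edf",
    "write_epochs_csv",
    "read_epochs_csv",
    "write_psd_csv",
]


def write_recording_csv(recording: Recording, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``<subject>.csv`` and ``<subject>_events.csv``; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = recording.samples.shape[1]
    df = pd.DataFrame(
        {"time_s": np.arange(n) / recording.fs}
        | {lab: recording.samples[i] for i, lab in enumerate(recording.channel_labels)}
    )
    samples_path = out_dir / f"{recording.subject_id}.csv"
    events_path = out_dir / f"{recording.subject_id}_events.csv"
    df.to_csv(samples_path, index=False, float_format="%.6f")
    pd.DataFrame(
        recording.events, columns=["stage", "start_sample", "end_sample"]
    ).to_csv(events_path, index=False)
    return samples_path, events_path


def read_recording_csv(
    samples_path: str | Path, events_path: str | Path | None = None
) -> Recording:
    """Read a recording from the CSV dialect written by this package."""
    samples_path = Path(samples_path)
    if events_path is None:
        events_path = samples_path.with_name(samples_path.stem + "_events.csv")
    df = pd.read_csv(samples_path)
    if "time_s" not in df.columns or len(df) < 2:
        raise ValueError(f"{samples_path} is not a recording CSV")
    # estimate fs from the full span (robust to per-sample rounding)
    span = float(df["time_s"].iloc[-1] - df["time_s"].iloc[0])
    fs = (len(df) - 1) / span
    channels = [c for c in df.columns if c != "time_s"]
    ev = pd.read_csv(events_path)
    events = [
        (str(r.stage), int(r.start_sample), int(r.end_sample))
        for r in ev.itertuples()
    ]
    rec = Recording(
        subject_id=samples_path.stem,
        channel_labels=channels,
        fs=round(fs, 3),
        samples=df[channels].to_numpy().T.copy(),
        events=events,
    )
    rec.validate()
    return rec


def read_recording_edf(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read an EDF/EDF+ recording; stage events are taken from annotations.

    Requires MNE (``pip install qeeg[edf]``).  Annotation descriptions are
    used verbatim as stage labels; durations are converted to half-open
    sample intervals.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extra
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    events = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        start = int(round(onset * fs))
        end = start + int(round(duration * fs))
        events.append((str(desc), start, end))
    rec = Recording(
        subject_id=subject_id or Path(path).stem,
        channel_labels=list(raw.ch_names),
        fs=fs,
        samples=raw.get_data(),
        events=sorted(events, key=lambda e: e[1]),
    )
    rec.validate()
    return rec


def write_epochs_csv(epoch_sets: list[StageEpochSet], path: str | Path) -> Path:
    """Long-format epochs file: subject, channel, stage, epoch_index,
    sample_index, value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for es in epoch_sets:
        n_ep, n_s = es.epochs.shape
        frames.append(
            pd.DataFrame(
                {
                    "subject": es.subject_id,
                    "channel": es.channel_label,
                    "stage": es.stage_label,
                    "epoch_index": np.repeat(np.arange(n_ep), n_s),
                    "sample_index": np.tile(np.arange(n_s), n_ep),
                    "value": es.epochs.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_psd_csv(spectrum, path: str | Path) -> Path:
    """Debug export of one epoch's PSD: columns freq_hz, power."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"freq_hz": spectrum.freqs, "power": spectrum.power}).to_csv(
        path, index=False
    )
    return path


def read_epochs_csv(path: str | Path, fs: float) -> list[StageEpochSet]:
    """Inverse of :func:`write_epochs_csv` (sampling rate is not stored in
    the long format and must be supplied)."""
    df = pd.read_csv(path)
    out = []
    for (subject, channel, stage), grp in df.groupby(
        ["subject", "channel", "stage"], sort=False
    ):
        n_ep = grp["epoch_index"].max() + 1
        n_s = grp["sample_index"].max() + 1
        epochs = (
            grp.sort_values(["epoch_index", "sample_index"])["value"]
            .to_numpy()
            .reshape(n_ep, n_s)
        )
        out.append(
            StageEpochSet(
                subject_id=str(subject),
                channel_label=str(channel),
                stage_label=str(stage),
                fs=fs,
                epochs=epochs,
            )
        )
    return out
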