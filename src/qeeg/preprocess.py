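"""Preprocessing chain: bandpass -> outlier replacement -> z-score -> epochs.

The chain is applied per channel and per stage segment, in that fixed
order, never across stage boundaries:

1. zero-phase 4th-order Butterworth bandpass, 0.5-35 Hz by default
   (removes slow drift and high-frequency noise);
2. robust outlier replacement: samples with |x - median| beyond
   ``outlier_k`` robust SDs (robust SD = 1.4826 x MAD) are replaced by the
   mean of the nearest non-outlier neighbour on each side;
3. z-score normalisation (sample SD, ddof=1) to remove subject/channel
   amplitude bias — the mean and SD are estimated per channel over the
   union of that channel's stage segments, so stages keep their relative
   amplitudes (an 8-s stage is not rescaled to the same variance as the
   60-s baseline, which would both erase genuine between-stage amplitude
   changes and couple epoch statistics to segment duration);
4. segmentation into contiguous non-overlapping 4-s epochs.

Bipolar channels FzCz = Fz - Cz and CzPz = Cz - Pz are derived from the
referential montage before the chain runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .simulate import Recording, STAGE_ORDER

__all__ = [
    "PreprocessConfig",
    "StageEpochSet",
    "CHANNEL_ORDER",
    "bandpass",
    "replace_outliers",
    "zscore",
    "derive_bipolar",
    "segment_stages",
]

#: output channel order used by all downstream tables
CHANNEL_ORDER = ("FP1", "FP2", "P3", "P4", "FzCz", "CzPz", "Fz", "Cz", "Pz")

_BIPOLAR_PAIRS = {"FzCz": ("Fz", "Cz"), "CzPz": ("Cz", "Pz")}


class FilterLengthError(ValueError):
    """Signal too short for the zero-phase filter."""


class DegenerateSignalError(ValueError):
    """Signal unusable (all samples outliers, or zero variance)."""


class MontageError(ValueError):
    """Required source channel missing for a bipolar derivation."""


class SegmentationError(ValueError):
    """Stage segment shorter than one epoch."""


class MissingStageError(KeyError):
    """Recording lacks an event marker for a requested stage."""


@dataclass(frozen=True)
class PreprocessConfig:
    band_low: float = 0.5
    band_high: float = 35.0
    epoch_seconds: float = 4.0
    outlier_k: float = 3.0
    filter_order: int = 4
    stages: tuple[str, ...] = STAGE_ORDER

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass
class StageEpochSet:
    """All fixed-length epochs of one subject x channel x stage.

    ``epochs`` has shape (n_epochs, epoch_samples); rows are contiguous,
    non-overlapping slices of the preprocessed stage segment.
    """

    subject_id: str
    channel_label: str
    stage_label: str
    fs: float
    epochs: np.ndarray = field(repr=False)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def bandpass(signal: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output has the input's length."""
    signal = np.asarray(signal, dtype=float)
    if fs <= 2 * cfg.band_high:
        raise ValueError(f"fs={fs} too low for band_high={cfg.band_high}")
    sos = _design(cfg.filter_order, cfg.band_low, cfg.band_high, fs)
    min_padlen = 3 * (2 * sos.shape[0] + 1)
    if signal.shape[-1] <= min_padlen:
        raise FilterLengthError(
            f"signal length {signal.shape[-1]} <= padlen {min_padlen} "
            "for zero-phase filter"
        )
    # generous reflection padding: the 0.5 Hz high-pass edge has a long
    # transient, and short stage segments must not be biased relative to
    # long ones by residual edge ringing
    padlen = min(signal.shape[-1] - 1, max(min_padlen, int(3 * fs / cfg.band_low)))
    return sosfiltfilt(sos, signal, axis=-1, padlen=padlen)


@lru_cache(maxsize=32)
def _design(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return 1.4826 * mad


def replace_outliers(signal: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Replace outliers by the mean of the nearest clean neighbours.

    A sample is an outlier when |x - median| > outlier_k x robust SD.
    Each outlier is replaced by the mean of the nearest non-outlier sample
    to its left and to its right (one side only at the edges).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("signal must have at least 3 samples")
    med = np.median(x)
    thresh = cfg.outlier_k * _robust_sd(x)
    bad = np.abs(x - med) > thresh
    if not bad.any():
        return x.copy()
    if bad.all():
        raise DegenerateSignalError("every sample flagged as outlier")
    out = x.copy()
    good_idx = np.flatnonzero(~bad)
    bad_idx = np.flatnonzero(bad)
    # nearest clean neighbour on each side via searchsorted on clean indices
    pos = np.searchsorted(good_idx, bad_idx)
    left = np.where(pos > 0, good_idx[np.maximum(pos - 1, 0)], -1)
    right = np.where(pos < good_idx.size, good_idx[np.minimum(pos, good_idx.size - 1)], -1)
    left_val = np.where(left >= 0, x[np.maximum(left, 0)], np.nan)
    right_val = np.where(right >= 0, x[np.maximum(right, 0)], np.nan)
    repl = np.nanmean(np.stack([left_val, right_val]), axis=0)
    out[bad_idx] = repl
    return out


def zscore(signal: np.ndarray) -> np.ndarray:
    """Standardise to mean 0, sample SD 1 (ddof=1)."""
    x = np.asarray(signal, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("zero-variance signal cannot be z-scored")
    return (x - x.mean()) / sd


def derive_bipolar(recording: Recording) -> Recording:
    """Append FzCz = Fz - Cz and CzPz = Cz - Pz to a referential recording.

    Output channels follow :data:`CHANNEL_ORDER`; the original referential
    channels are carried through unchanged.
    """
    labels = recording.channel_labels
    for derived, (a, b) in _BIPOLAR_PAIRS.items():
        for src in (a, b):
            if src not in labels:
                raise MontageError(f"channel {src!r} required for {derived} missing")
    index = {lab: i for i, lab in enumerate(labels)}
    rows = []
    out_labels = []
    for lab in CHANNEL_ORDER:
        if lab in _BIPOLAR_PAIRS:
            a, b = _BIPOLAR_PAIRS[lab]
            rows.append(recording.samples[index[a]] - recording.samples[index[b]])
        elif lab in index:
            rows.append(recording.samples[index[lab]])
        else:
            raise MontageError(f"channel {lab!r} missing from recording")
        out_labels.append(lab)
    return Recording(
        subject_id=recording.subject_id,
        channel_labels=out_labels,
        fs=recording.fs,
        samples=np.vstack(rows),
        events=list(recording.events),
    )


def preprocess_segment(
    segment: np.ndarray, fs: float, cfg: PreprocessConfig
) -> np.ndarray:
    """Full chain (bandpass -> outlier replacement -> z-score) on one
    isolated single-channel segment (z-score over that segment)."""
    return zscore(replace_outliers(bandpass(segment, fs, cfg), cfg))


def segment_stages(
    recording: Recording, cfg: PreprocessConfig
) -> list[StageEpochSet]:
    """Preprocess and epoch every channel x stage of a recording.

    The recording must already contain the 9-channel montage (call
    :func:`derive_bipolar` first if it is referential).  Filtering and
    outlier replacement run per stage segment (never across stage
    boundaries); the z-score mean/SD are estimated per channel over the
    concatenation of its cleaned stage segments and applied to each, so
    the normalisation removes subject/channel amplitude bias without
    flattening between-stage amplitude differences.  Each segment is then
    cut into floor(duration / epoch_seconds) contiguous 4-s epochs.
    """
    events = {stage: (s, e) for stage, s, e in recording.events}
    for stage in cfg.stages:
        if stage not in events:
            raise MissingStageError(f"recording has no event for stage {stage!r}")
    n_epoch = int(round(cfg.epoch_seconds * recording.fs))
    out: list[StageEpochSet] = []
    for ci, channel in enumerate(recording.channel_labels):
        cleaned: dict[str, np.ndarray] = {}
        for stage in cfg.stages:
            start, end = events[stage]
            seg = recording.samples[ci, start:end]
            if seg.size < n_epoch:
                raise SegmentationError(
                    f"stage {stage!r} segment ({seg.size} samples) shorter than "
                    f"one {n_epoch}-sample epoch"
                )
            cleaned[stage] = replace_outliers(
                bandpass(seg, recording.fs, cfg), cfg
            )
        pooled = np.concatenate(list(cleaned.values()))
        mu = pooled.mean()
        sd = pooled.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateSignalError(
                f"channel {channel!r} has zero variance across stages"
            )
        for stage in cfg.stages:
            clean = (cleaned[stage] - mu) / sd
            n = clean.size // n_epoch
            epochs = clean[: n * n_epoch].reshape(n, n_epoch)
            out.append(
                StageEpochSet(
                    subject_id=recording.subject_id,
                    channel_label=channel,
                    stage_label=stage,
                    fs=recording.fs,
                    epochs=epochs,
                )
            )
    return out
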