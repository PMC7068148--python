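"""The 30-feature battery and its batch API.

One :data:`FEATURE_ORDER` fixes the canonical row order of every output
table: 5 time-domain, 9 frequency-domain, 16 wavelet-domain features.
``epoch_features`` computes the battery for a single epoch through the
per-feature modules; ``extract_features`` runs the battery over a list of
:class:`~qeeg.preprocess.StageEpochSet` with the spectral, Hjorth and
wavelet parts vectorised across epochs (the results are identical to the
per-epoch route; only approximate entropy is computed epoch-by-epoch, in
its compiled kernel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import pywt

from .features_spectral import (
    BANDS,
    SPECTRAL_FEATURES,
    TOTAL_BAND,
    spectral_features,
)
from .features_time import TIME_FEATURES, approx_entropy, time_features
from .features_wavelet import (
    WAVELET_BANDS,
    WAVELET_FEATURES,
    wavelet_features_from_epoch,
)
from .preprocess import StageEpochSet

__all__ = ["FeatureConfig", "FEATURE_ORDER", "epoch_features", "extract_features"]

#: canonical feature order of all comparison tables
FEATURE_ORDER = TIME_FEATURES + SPECTRAL_FEATURES + WAVELET_FEATURES


@dataclass(frozen=True)
class FeatureConfig:
    apen_m: int = 2
    apen_r_factor: float = 0.2
    wavelet_name: str = "db4"
    boundary_mode: str = "periodization"


def epoch_features(
    epoch: np.ndarray, fs: float, cfg: FeatureConfig = FeatureConfig()
) -> dict:
    """All 30 features of one epoch, keyed by :data:`FEATURE_ORDER` names."""
    out = time_features(epoch, m=cfg.apen_m, r_factor=cfg.apen_r_factor)
    out.update(spectral_features(epoch, fs))
    out.update(
        wavelet_features_from_epoch(epoch, cfg.wavelet_name, cfg.boundary_mode)
    )
    return {name: out[name] for name in FEATURE_ORDER}


def _batch_time(epochs: np.ndarray, cfg: FeatureConfig) -> dict[str, np.ndarray]:
    x = epochs
    var_x = x.var(axis=1)
    dx = np.diff(x, axis=1)
    ddx = np.diff(dx, axis=1)
    var_dx = dx.var(axis=1)
    var_ddx = ddx.var(axis=1)
    mobility = np.sqrt(var_dx / var_x)
    complexity = np.sqrt(var_ddx / var_dx) / mobility
    apen = np.array(
        [approx_entropy(row, m=cfg.apen_m, r_factor=cfg.apen_r_factor) for row in x]
    )
    return {
        "hjorth_activity": var_x,
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "approximate_entropy": apen,
        "rms_value": np.sqrt(np.mean(x * x, axis=1)),
    }


def _batch_spectral(epochs: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    n = epochs.shape[1]
    spec = np.abs(np.fft.rfft(epochs, axis=1)) ** 2
    power = spec / (n * n) * (n / fs)
    if n % 2 == 0:
        power[:, 1:-1] *= 2.0
    else:
        power[:, 1:] *= 2.0
    power = power / power.max(axis=1, keepdims=True)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = freqs[1] - freqs[0]
    in_band = (freqs >= TOTAL_BAND[0]) & (freqs < TOTAL_BAND[1])
    p_in = power[:, in_band]
    f_in = freqs[in_band]
    total = p_in.sum(axis=1) * df
    out = {"total_band_power": total}
    for name, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        out[f"rel_{name}_power"] = power[:, mask].sum(axis=1) * df / total
    q = p_in / p_in.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), 0.0)
    out["specentropy"] = -(q * logq).sum(axis=1) / np.log(q.shape[1])
    cum = np.cumsum(p_in, axis=1) / p_in.sum(axis=1, keepdims=True)
    last = f_in.size - 1
    med_idx = np.minimum((cum >= 0.5).argmax(axis=1), last)
    sef_idx = np.minimum((cum >= 0.95).argmax(axis=1), last)
    out["median_frequency"] = f_in[med_idx]
    out["spectral_edge_frequency"] = f_in[sef_idx]
    out["mean_frequency"] = (f_in * p_in).sum(axis=1) / p_in.sum(axis=1)
    return out


def _batch_wavelet(epochs: np.ndarray, cfg: FeatureConfig) -> dict[str, np.ndarray]:
    coeffs = pywt.wavedec(
        epochs, cfg.wavelet_name, mode=cfg.boundary_mode, level=5, axis=1
    )
    named = dict(zip(("a5", "d5", "d4", "d3"), coeffs[:4]))
    out: dict[str, np.ndarray] = {}
    for band in WAVELET_BANDS:
        c = named[band]
        out[f"mean_{band}"] = c.mean(axis=1)
        out[f"sd_{band}"] = c.std(axis=1, ddof=1)
        out[f"max_{band}"] = c.max(axis=1)
        out[f"min_{band}"] = c.min(axis=1)
    return out


def extract_features(
    epoch_sets: Iterable[StageEpochSet], cfg: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Long-format feature table over many epoch sets.

    Returns columns: subject, channel, stage, epoch_index, feature, value;
    features appear in :data:`FEATURE_ORDER`.
    """
    sets = list(epoch_sets)
    if not sets:
        raise ValueError("no epoch sets supplied")
    fs = sets[0].fs
    if any(es.fs != fs for es in sets):
        raise ValueError("all epoch sets must share one sampling rate")
    stacked = np.concatenate([es.epochs for es in sets], axis=0)
    cols: dict[str, np.ndarray] = {}
    cols.update(_batch_time(stacked, cfg))
    cols.update(_batch_spectral(stacked, fs))
    cols.update(_batch_wavelet(stacked, cfg))

    counts = np.array([es.n_epochs for es in sets])
    total = int(counts.sum())
    subj = np.repeat([es.subject_id for es in sets], counts)
    chan = np.repeat([es.channel_label for es in sets], counts)
    stage = np.repeat([es.stage_label for es in sets], counts)
    eidx = np.concatenate([np.arange(c) for c in counts])

    n_feat = len(FEATURE_ORDER)
    df = pd.DataFrame(
        {
            "subject": np.tile(subj, n_feat),
            "channel": np.tile(chan, n_feat),
            "stage": np.tile(stage, n_feat),
            "epoch_index": np.tile(eidx, n_feat),
            "feature": pd.Categorical(
                np.repeat(list(FEATURE_ORDER), total), categories=FEATURE_ORDER
            ),
            "value": np.concatenate([cols[name] for name in FEATURE_ORDER]),
        }
    )
    return df
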