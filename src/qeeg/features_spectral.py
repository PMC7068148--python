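"""Frequency-domain epoch features from a max-normalised periodogram.

The power spectral density of a 4-s epoch is the one-sided periodogram
(the FFT of the biased autocorrelation sequence — the Wiener-Khinchin
identity makes the two routes equal), scaled so that the rectangle-rule
integral of the raw density equals the epoch's mean square (Parseval),
then divided by its maximum so that max(power) = 1.

From the normalised PSD, restricted to the analysis band 0.5-30 Hz:

* total band power (normalised power x Hz, rectangle rule);
* relative delta/theta/alpha/beta power over the half-open partition
  [0.5,4), [4,8), [8,15), [15,30) — the four fractions sum to 1;
* spectral entropy (Shannon entropy of the in-band power distribution,
  normalised by log of the bin count, so flat spectrum -> 1);
* median frequency, 95% spectral edge frequency (smallest bin frequency
  whose cumulative in-band power reaches 50% / 95%), and the
  power-weighted mean frequency.

All relative quantities are invariant to any positive rescaling of the
PSD, so the max-normalisation affects only ``total_band_power``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Psd",
    "psd",
    "band_powers",
    "spectral_entropy",
    "spectral_frequencies",
    "spectral_features",
    "SPECTRAL_FEATURES",
    "BANDS",
    "TOTAL_BAND",
]

#: half-open band partition [lo, hi) of the analysis range
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
}
TOTAL_BAND = (0.5, 30.0)

SPECTRAL_FEATURES = (
    "total_band_power",
    "rel_delta_power",
    "rel_theta_power",
    "rel_alpha_power",
    "rel_beta_power",
    "specentropy",
    "median_frequency",
    "spectral_edge_frequency",
    "mean_frequency",
)


class ResolutionError(ValueError):
    """Epoch too short to resolve the analysis band."""


class DegenerateSpectrumError(ValueError):
    """No power in the analysis band."""


@dataclass
class Psd:
    """One-sided PSD on the grid 0..fs/2 with resolution fs/N."""

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def _raw_periodogram(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram density: sum(power) * df == mean(epoch**2)."""
    x = np.asarray(epoch, dtype=float)
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2
    # density scaling: |X_k|^2 / N^2 per (two-sided) bin of width fs/N
    power = spec / (n * n) * (n / fs)
    if n % 2 == 0:
        power[1:-1] *= 2.0  # fold negative frequencies, Nyquist unpaired
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def psd(epoch: np.ndarray, fs: float, normalize: bool = True) -> Psd:
    """Max-normalised one-sided periodogram of one epoch.

    Requires at least one second of data (frequency resolution <= 1 Hz) so
    that the 0.5 Hz band edge is resolvable.
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < fs:
        raise ResolutionError("epoch must span at least one second")
    freqs, power = _raw_periodogram(x, fs)
    if normalize:
        peak = power.max()
        if peak <= 0:
            raise DegenerateSpectrumError("all-zero spectrum")
        power = power / peak
    return Psd(freqs=freqs, power=power, normalized=normalize)


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs < hi)


def band_powers(spectrum: Psd) -> dict:
    """Total 0.5-30 Hz power and the four relative band powers."""
    f, p = spectrum.freqs, spectrum.power
    df = spectrum.df
    total_mask = _band_mask(f, *TOTAL_BAND)
    total = p[total_mask].sum() * df
    if total <= 0:
        raise DegenerateSpectrumError("zero total power in 0.5-30 Hz")
    out = {"total_band_power": float(total)}
    for name, (lo, hi) in BANDS.items():
        out[f"rel_{name}_power"] = float(p[_band_mask(f, lo, hi)].sum() * df / total)
    return out


def spectral_entropy(spectrum: Psd) -> float:
    """Normalised Shannon entropy of the in-band power distribution."""
    p = spectrum.power[_band_mask(spectrum.freqs, *TOTAL_BAND)]
    total = p.sum()
    if total <= 0:
        raise DegenerateSpectrumError("zero total power in 0.5-30 Hz")
    q = p / total
    nz = q > 0
    h = -np.sum(q[nz] * np.log(q[nz]))
    return float(h / np.log(q.size))


def spectral_frequencies(spectrum: Psd) -> tuple[float, float, float]:
    """(median frequency, SEF95, power-weighted mean frequency) in Hz.

    Median and edge frequencies use the smallest-bin >= threshold
    convention on the cumulative in-band power.
    """
    mask = _band_mask(spectrum.freqs, *TOTAL_BAND)
    f = spectrum.freqs[mask]
    p = spectrum.power[mask]
    total = p.sum()
    if total <= 0:
        raise DegenerateSpectrumError("zero total power in 0.5-30 Hz")
    cum = np.cumsum(p) / total
    last = f.size - 1
    median = float(f[min(np.searchsorted(cum, 0.5), last)])
    sef95 = float(f[min(np.searchsorted(cum, 0.95), last)])
    mean = float(np.sum(f * p) / total)
    return median, sef95, mean


def spectral_features(epoch: np.ndarray, fs: float) -> dict:
    """All nine frequency-domain features of one epoch, by name."""
    spectrum = psd(epoch, fs)
    out = band_powers(spectrum)
    out["specentropy"] = spectral_entropy(spectrum)
    med, sef, mean = spectral_frequencies(spectrum)
    out["median_frequency"] = med
    out["spectral_edge_frequency"] = sef
    out["mean_frequency"] = mean
    return out
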