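"""Synthetic anaesthesia-EEG cohort generator.

Builds multi-subject, stage-marked, multichannel recordings whose only
controlled structure is band power: each stage of the anaesthesia timeline
(baseline, start of induction, loss of consciousness, intubation,
pre-incision, incision) is synthesised as a sum of unit-variance
band-limited Gaussian noises (delta <4 Hz, theta 4-8 Hz, alpha 8-15 Hz,
beta 15-30 Hz) scaled by per-stage amplitude multipliers, plus a broadband
1/f "pink" floor.  Inter-subject variability enters as log-normal
multipliers on the band amplitudes, drawn once per subject.

The generator makes no attempt at EEG microstructure (no spindles,
K-complexes or burst suppression); it provides exactly the band-power
contrasts that the downstream feature battery and paired statistics are
designed to detect, so the whole pipeline can be exercised and calibrated
without patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "BandProfile",
    "StageScenario",
    "Recording",
    "STAGE_ORDER",
    "UNIPOLAR_CHANNELS",
    "BAND_EDGES",
    "make_band_noise",
    "make_pink_noise",
    "generate_subject",
    "generate_cohort",
    "default_scenario",
    "null_scenario",
]

#: the six anaesthesia stages, in temporal order
STAGE_ORDER = (
    "baseline",
    "induction_start",
    "loc",
    "intubation",
    "preincision",
    "incision",
)

#: scalp electrodes recorded referentially (10-20 system)
UNIPOLAR_CHANNELS = ("FP1", "FP2", "P3", "P4", "Fz", "Cz", "Pz")

#: canonical band edges (Hz) used both here and by the spectral features
BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
}

_EPOCH_SECONDS = 4.0  # stage durations must tile into 4-s epochs
_MICROVOLT_SCALE = 10.0  # arbitrary microvolt-like output scale


class BandDefinitionError(ValueError):
    """Invalid band edges for band-limited noise."""


class ScenarioError(ValueError):
    """Invalid stage scenario."""


class CohortSizeError(ValueError):
    """Cohort smaller than the minimum usable size."""


@dataclass(frozen=True)
class BandProfile:
    """Linear amplitude multipliers for the four EEG bands plus a 1/f floor.

    Each multiplier scales a unit-variance band-limited noise, so the
    *power* contributed by band ``b`` is ``amp_b ** 2`` (before the
    per-subject log-normal multiplier).
    """

    delta_amp: float
    theta_amp: float
    alpha_amp: float
    beta_amp: float
    pink_floor: float = 0.0

    def __post_init__(self) -> None:
        amps = self.amplitudes() + (self.pink_floor,)
        if not all(math.isfinite(a) and a >= 0 for a in amps):
            raise ScenarioError("band amplitudes must be finite and non-negative")
        if not any(a > 0 for a in amps):
            raise ScenarioError("at least one band amplitude must be positive")

    def amplitudes(self) -> tuple[float, float, float, float]:
        return (self.delta_amp, self.theta_amp, self.alpha_amp, self.beta_amp)

    def scaled(self, factor: float) -> "BandProfile":
        """Profile with every amplitude (including the pink floor) scaled."""
        return BandProfile(
            self.delta_amp * factor,
            self.theta_amp * factor,
            self.alpha_amp * factor,
            self.beta_amp * factor,
            self.pink_floor * factor,
        )


_DEFAULT_DURATIONS = {
    "baseline": 60.0,
    "induction_start": 8.0,
    "loc": 8.0,
    "intubation": 8.0,
    "preincision": 8.0,
    "incision": 4.0,
}


@dataclass(frozen=True)
class StageScenario:
    """Full description of one simulated study condition.

    ``stage_profiles`` maps every stage label in :data:`STAGE_ORDER` to a
    :class:`BandProfile`; ``stage_durations`` gives seconds per stage (each
    a multiple of the 4-s epoch); ``subject_variability_sd`` is the SD of
    the per-subject log-normal band-amplitude multipliers; ``gap_seconds``
    of unmarked transition signal is inserted between stages (mimicking
    manual event marking: samples outside events exist but are never
    analysed).
    """

    stage_profiles: dict[str, BandProfile]
    stage_durations: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DURATIONS)
    )
    subject_variability_sd: float = 0.2
    seed: int = 0
    fs: float = 256.0
    gap_seconds: float = 1.0
    channels: tuple[str, ...] = UNIPOLAR_CHANNELS

    def __post_init__(self) -> None:
        missing = set(STAGE_ORDER) - set(self.stage_profiles)
        if missing:
            raise ScenarioError(f"missing stage profiles: {sorted(missing)}")
        extra = set(self.stage_profiles) - set(STAGE_ORDER)
        if extra:
            raise ScenarioError(f"unknown stage labels: {sorted(extra)}")
        for stage in STAGE_ORDER:
            dur = self.stage_durations.get(stage)
            if dur is None or dur <= 0:
                raise ScenarioError(f"stage {stage!r} needs a positive duration")
            n_epochs = dur / _EPOCH_SECONDS
            if abs(n_epochs - round(n_epochs)) > 1e-9:
                raise ScenarioError(
                    f"duration of {stage!r} ({dur} s) must be a multiple of "
                    f"the {_EPOCH_SECONDS:.0f}-s epoch"
                )
        if self.subject_variability_sd < 0:
            raise ScenarioError("subject_variability_sd must be >= 0")
        if self.fs <= 60:
            raise ScenarioError("sampling rate too low for the 0.5-30 Hz design")


@dataclass
class Recording:
    """One subject's multichannel EEG with stage event markers.

    ``samples`` is channel x time; ``events`` is a list of
    ``(stage_label, start_sample, end_sample)`` with half-open
    ``[start, end)`` intervals, disjoint and in temporal order.
    """

    subject_id: str
    channel_labels: list[str]
    fs: float
    samples: np.ndarray
    events: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channel x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels must match samples rows")

    def validate(self) -> None:
        """Check event ordering/disjointness and sample finiteness."""
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        prev_end = 0
        n = self.samples.shape[1]
        for stage, start, end in self.events:
            if not (0 <= start < end <= n):
                raise ValueError(f"event {stage!r} outside sample range")
            if start < prev_end:
                raise ValueError(f"event {stage!r} overlaps its predecessor")
            prev_end = end

    def stage_slice(self, stage: str) -> np.ndarray:
        """channel x time samples of one marked stage."""
        for label, start, end in self.events:
            if label == stage:
                return self.samples[:, start:end]
        raise KeyError(f"no event for stage {stage!r}")


@lru_cache(maxsize=64)
def _band_sos(band_low: float, band_high: float, fs: float) -> np.ndarray:
    return butter(4, [band_low, band_high], btype="bandpass", fs=fs, output="sos")


def _band_noise_block(
    band_low: float,
    band_high: float,
    shape: tuple[int, ...],
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited unit-variance noise, vectorised over leading axes."""
    if not (0 <= band_low < band_high <= fs / 2):
        raise BandDefinitionError(
            f"invalid band edges ({band_low}, {band_high}) for fs={fs}"
        )
    n_samples = shape[-1]
    if n_samples < 64:
        raise BandDefinitionError("n_samples must be >= 64")
    pad = 2 * int(fs)  # discard filter warm-up at both ends
    white = rng.standard_normal(shape[:-1] + (n_samples + 2 * pad // 2,))
    low = max(band_low, 1e-3)  # Butterworth bandpass needs a positive low edge
    x = sosfiltfilt(_band_sos(low, band_high, fs), white, axis=-1)
    x = x[..., pad // 2 : pad // 2 + n_samples]
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise BandDefinitionError("degenerate band noise (zero variance)")
    return x / sd


def make_band_noise(
    band_low: float,
    band_high: float,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [band_low, band_high] Hz.

    White noise is passed through the same zero-phase 4th-order Butterworth
    bandpass used by the preprocessing stage, then rescaled to unit sample
    variance.  For ``n_samples >= 1024`` at fs=256 the expected in-band
    fraction of periodogram power is >= 90% for every canonical band (and
    holds per-realisation for the wider bands; narrow low-frequency bands
    have few periodogram bins and fluctuate by a few percent across seeds).
    """
    return _band_noise_block(band_low, band_high, (int(n_samples),), fs, rng)


def make_pink_noise(
    n_samples: int, fs: float, rng: np.random.Generator, n_rows: int | None = None
) -> np.ndarray:
    """Unit-variance 1/f-power noise via FFT amplitude shaping (DC removed)."""
    shape = (n_samples,) if n_rows is None else (n_rows, n_samples)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    return x / x.std(axis=-1, keepdims=True)


def _stage_block(
    profile: BandProfile,
    multipliers: np.ndarray,
    n_channels: int,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """channel x time signal block for one stage."""
    sig = np.zeros((n_channels, n_samples))
    n_gen = max(n_samples, 64)
    for amp, mult, (lo, hi) in zip(
        profile.amplitudes(), multipliers, BAND_EDGES.values()
    ):
        a = amp * mult
        if a > 0:
            sig += a * _band_noise_block(lo, hi, (n_channels, n_gen), fs, rng)[
                :, :n_samples
            ]
    if profile.pink_floor > 0:
        sig += profile.pink_floor * make_pink_noise(n_gen, fs, rng, n_channels)[
            :, :n_samples
        ]
    return sig * _MICROVOLT_SCALE


def generate_subject(
    scenario: StageScenario,
    subject_id: str,
    rng: np.random.Generator,
) -> Recording:
    """Synthesise one subject's recording under a scenario.

    The subject's four log-normal band multipliers are drawn once and
    applied to every stage, so stage contrasts within a subject reflect the
    stage profiles, while between-subject spread reflects
    ``subject_variability_sd``.  A short unmarked transition segment is
    inserted between consecutive stages.
    """
    sd = scenario.subject_variability_sd
    if sd > 0:
        multipliers = np.exp(rng.normal(0.0, sd, size=4))
    else:
        multipliers = np.ones(4)
    fs = scenario.fs
    n_gap = int(round(scenario.gap_seconds * fs))
    chunks: list[np.ndarray] = []
    events: list[tuple[str, int, int]] = []
    cursor = 0
    n_ch = len(scenario.channels)
    for k, stage in enumerate(STAGE_ORDER):
        profile = scenario.stage_profiles[stage]
        n = int(round(scenario.stage_durations[stage] * fs))
        chunks.append(_stage_block(profile, multipliers, n_ch, n, fs, rng))
        events.append((stage, cursor, cursor + n))
        cursor += n
        if n_gap > 0 and k < len(STAGE_ORDER) - 1:
            nxt = scenario.stage_profiles[STAGE_ORDER[k + 1]]
            chunks.append(_stage_block(nxt, multipliers, n_ch, n_gap, fs, rng))
            cursor += n_gap
    rec = Recording(
        subject_id=subject_id,
        channel_labels=list(scenario.channels),
        fs=fs,
        samples=np.concatenate(chunks, axis=1),
        events=events,
    )
    rec.validate()
    return rec


def generate_cohort(scenario: StageScenario, n_subjects: int = 19) -> list[Recording]:
    """Generate a reproducible cohort; per-subject RNG streams are spawned
    from the scenario seed so the cohort is independent of generation order."""
    if n_subjects < 2:
        raise CohortSizeError("a cohort needs at least 2 subjects")
    master = np.random.SeedSequence(scenario.seed)
    children = master.spawn(n_subjects)
    width = max(2, len(str(n_subjects)))
    return [
        generate_subject(scenario, f"S{k + 1:0{width}d}", np.random.default_rng(child))
        for k, child in enumerate(children)
    ]


def default_scenario(seed: int = 0, **overrides) -> StageScenario:
    """Scenario encoding the qualitative stage effects under study.

    Loss of consciousness: delta amplitude up, theta/alpha/beta down.
    Intubation: broad global attenuation relative to the LoC state.
    Incision: delta up and alpha down relative to pre-incision
    ("paradoxical arousal").  Start of induction carries a mild biphasic
    signature (delta slightly down, alpha/beta slightly up).  Amplitudes
    are declared defaults (see docs/methods.md); the underlying study
    reports directions only.
    """
    profiles = {
        "baseline": BandProfile(1.0, 0.7, 0.9, 0.5, pink_floor=0.3),
        "induction_start": BandProfile(0.8, 0.7, 1.1, 0.7, pink_floor=0.3),
        "loc": BandProfile(2.0, 0.5, 0.45, 0.25, pink_floor=0.3),
        "intubation": BandProfile(1.3, 0.33, 0.3, 0.17, pink_floor=0.2),
        "preincision": BandProfile(1.4, 0.45, 0.5, 0.25, pink_floor=0.25),
        "incision": BandProfile(2.2, 0.4, 0.3, 0.22, pink_floor=0.25),
    }
    return StageScenario(stage_profiles=profiles, seed=seed, **overrides)


def null_scenario(seed: int = 0, **overrides) -> StageScenario:
    """Scenario with identical profiles in every stage (no true effects);
    used for type-I-error calibration of the comparison tables."""
    base = BandProfile(1.0, 0.7, 0.9, 0.5, pink_floor=0.3)
    profiles = {stage: base for stage in STAGE_ORDER}
    return StageScenario(stage_profiles=profiles, seed=seed, **overrides)
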