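# Methods

`qeeg` quantifies how scalp EEG changes across anaesthesia stages. The
pipeline has four layers — a synthetic cohort generator, a preprocessing
chain, a 30-feature battery per 4-s epoch, and a paired nonparametric
comparison layer — and this note records the model behind each layer, the
parameters that matter, and the design choices that were genuinely open.

## Study conditions

The analysis is organised around six stages of the anaesthesia timeline:
resting baseline, start of induction, loss of consciousness (LoC),
intubation, pre-incision, and incision. Default segment durations are
60 s (baseline), 8 s (induction start, LoC, intubation, pre-incision) and
4 s (incision); at the 4-s epoch length this yields 15/2/2/2/2/1 epochs
per stage. Recordings are sampled at 256 Hz on seven referential 10-20
channels (FP1, FP2, P3, P4, Fz, Cz, Pz), from which two bipolar channels
(FzCz = Fz − Cz, CzPz = Cz − Pz) are derived, giving the 9-channel axis
of every output table. The default cohort size is 19 subjects, and three
paired contrasts are tested: baseline vs LoC, pre vs post intubation
(the LoC segment serving as the pre-intubation state), and pre vs post
incision.

## Synthetic cohort generator

Each stage's signal is a sum of four unit-variance band-limited Gaussian
noises — delta [0.5, 4), theta [4, 8), alpha [8, 15), beta [15, 30) Hz —
scaled by per-stage amplitude multipliers, plus a broadband 1/f (pink)
floor. Band noise is produced by the same zero-phase 4th-order
Butterworth bandpass family used in preprocessing (one filter
implementation, fewer discrepancies); because each band noise has unit
variance, band `b` contributes power `amp_b²` and the rank order of
relative band powers tracks the rank order of squared amplitudes.

Inter-subject variability is a log-normal multiplier per band (SD of the
log defaults to 0.2), drawn once per subject and applied to every stage —
multiplicative, always positive, and cancelling in within-subject
contrasts, which is the natural model for relative-power analysis.
Per-subject RNG streams are spawned from the scenario seed
(`numpy.random.SeedSequence`), so a cohort is reproducible regardless of
generation order. A 1-s transition segment is generated between stages
but excluded from the event markers, mimicking manually marked events;
samples outside events are never analysed.

The default stage profiles encode the qualitative effect directions under
study (amplitudes per band delta/theta/alpha/beta, plus pink floor):

| stage            | delta | theta | alpha | beta | pink |
|------------------|-------|-------|-------|------|------|
| baseline         | 1.0   | 0.7   | 0.9   | 0.5  | 0.3  |
| induction_start  | 0.8   | 0.7   | 1.1   | 0.7  | 0.3  |
| loc              | 2.0   | 0.5   | 0.45  | 0.25 | 0.3  |
| intubation       | 1.3   | 0.33  | 0.3   | 0.17 | 0.2  |
| preincision      | 1.4   | 0.45  | 0.5   | 0.25 | 0.25 |
| incision         | 2.2   | 0.4   | 0.3   | 0.22 | 0.25 |

LoC doubles delta amplitude and attenuates the faster bands; intubation
is a roughly global attenuation of the LoC state; incision raises delta
and lowers alpha relative to pre-incision (the "paradoxical arousal"
signature); induction start carries a mild biphasic signature (delta
down, alpha/beta up). The underlying study reports only directions and
p-values, never effect sizes, so these amplitudes are declared defaults:
they were chosen from the band-power model so that a 19-subject paired
comparison recovers the injected directions with high power, and they are
not calibrated to any patient dataset.

What the generator does **not** emulate: EEG microstructure (spindles,
K-complexes, burst suppression), artefacts (blinks, EMG — the analysed
windows are artefact-free by construction), volume-conduction correlation
between channels (channels are independent realisations sharing subject
multipliers), and nonstationarity within a stage. Passing tests therefore
demonstrate that the pipeline recovers band-power structure and calibrates
correctly under its own model; they do not validate performance against
real patient EEG.

## Preprocessing

Per channel and per stage segment, in fixed order: (1) zero-phase
4th-order Butterworth bandpass 0.5–35 Hz (`sosfiltfilt`); (2) robust
outlier replacement; (3) z-score normalisation; (4) segmentation into
contiguous non-overlapping 4-s epochs (floor(duration/4) per stage, no
overlap anywhere). Filtering never crosses a stage boundary. Event
intervals are half-open `[start, end)` with 0-based sample indices.

**Outlier rule.** A sample is an outlier when |x − median| >
k·1.4826·MAD (k = 3 by default); each outlier is replaced by the mean of
the nearest non-outlier neighbour on each side (one side at the edges).
The rule is deterministic and robust; note that when MAD = 0 every sample
off the median is flagged, which is the intended behaviour for spike-like
contamination of an otherwise flat signal.

**Filter padding.** `sosfiltfilt` is run with reflection padding of
about `3·fs/band_low` samples (≈6 s at the 0.5 Hz edge) instead of the
library default (~27 samples). The high-pass transient is long at 0.5 Hz,
and with short padding an 8-s segment carries proportionally more edge
ringing than the 60-s baseline — enough to bias spectral features of
short stages systematically. With the long padding, no duration-dependent
spectral bias is detectable in null simulations.

**Z-score scope.** The mean and SD are estimated per channel over the
union of that channel's cleaned stage segments and then applied to each
segment. Two alternatives were considered. Per-stage scoring (each
segment forced to unit variance) erases all between-stage amplitude
information — Hjorth activity, RMS and total power could then never
differ between stages — and, worse, it couples epoch statistics to
segment duration: a 2-epoch segment constrained to unit variance has
systematically different epoch-level variance/RMS than a 15-epoch one,
which a paired signed-rank test across 19 subjects detects as a bogus
"effect" in null simulations (rejection rates up to ~50% for RMS).
Recording-level scoring removes the subject/channel amplitude bias that
normalisation is for, while preserving relative amplitudes between
stages; under a no-effect scenario it restores the nominal test level.

## Feature battery (30 per epoch)

**Time domain (5).** Hjorth activity = var(x); mobility =
sqrt(var(Δx)/var(x)); complexity = mobility(Δx)/mobility(x), with Δ the
first difference (no sampling-rate scaling — the constant cancels in rank
statistics; for a sampled sinusoid of frequency f, mobility is exactly
2·sin(πf/fs) and complexity 1). Approximate entropy uses the classic
construction with self-matches included: ApEn(m, r) = Φ_m − Φ_{m+1},
Chebyshev distance, m = 2 and r = 0.2·SD(epoch) (the field-standard
defaults; the epoch SD is the population SD). The implementation sorts
templates by first coordinate so only first-coordinate-compatible pairs
are compared; the counts are exactly those of the naive O(N²) loop, which
the tests verify to 1e-10. RMS is sqrt(mean(x²)).

**Frequency domain (9).** The PSD of an epoch is the one-sided
periodogram — identically the FFT of the biased autocorrelation sequence
(Wiener–Khinchin), which the tests verify — scaled so the raw density
integrates to the mean square (Parseval) and then divided by its maximum
(so max(power) = 1). A single rectangular-window periodogram is used per
4-s epoch: epochs are already short analysis units, so no Welch averaging
or tapering is applied. Bands partition [0.5, 30) half-open, so the four
relative powers sum to exactly 1; total band power integrates the
normalised density over 0.5–30 Hz (the union of the four bands — the
30–35 Hz sliver belongs to no band). Because total power is computed
*after* max-normalisation it behaves as a peakedness measure (a sharper
spectrum lowers it), not as absolute power; the amplitude information
lives in activity/RMS and the wavelet statistics. Spectral entropy is the
Shannon entropy of the in-band power distribution normalised by log(bin
count) (natural log; the base cancels). Median and 95% spectral edge
frequency use the smallest-bin-≥-threshold convention on the cumulative
in-band power; mean frequency is power-weighted.

**Wavelet domain (16).** Five-level Mallat cascade with a Daubechies
mother wavelet (db4 default — a common qEEG choice; order configurable).
At 256 Hz the retained bands are a5 (≈0–4 Hz), d5 (4–8), d4 (8–16) and
d3 (16–32); d2/d1 (32–128 Hz) lie above the 35 Hz filter edge and are
discarded. d4's dyadic band is 8–16 Hz, not the 8–15 Hz alpha definition;
no correction is attempted. Features are mean, SD (ddof = 1), maximum and
minimum of the **signed** coefficients per retained band. Boundary
handling defaults to periodization: the periodized DWT is orthogonal, so
coefficient lengths halve exactly per level (32/32/64/128/256/512 for
1024 samples) and energy is conserved to rounding, keeping the per-band
statistics free of boundary-extension inflation on short epochs;
symmetric extension is available by configuration where edge artefacts
matter more than orthogonality.

## Statistics

Per-epoch features are averaged (arithmetic mean) within
subject × channel × stage. For each contrast, each of the 30 × 9 cells is
tested with a two-sided Wilcoxon signed-rank test on post − pre across
subjects: zero differences are discarded (Wilcoxon's original rule), tied
absolute differences receive midranks, and for n ≤ 25 remaining pairs the
p-value comes from exact enumeration of the null distribution of the
signed-rank sum — a subset-sum convolution over doubled midranks, which
are integers even with ties; both tails are inclusive and the p-value is
twice the smaller tail, capped at 1. Above n = 25, a normal approximation
with tie correction and a 0.5 continuity correction is used. The exact
route matters because the design's n = 19 sits squarely in the
small-sample regime.

Direction of change is the sign of the median paired difference over all
pairs (including zeros); "none" iff the median difference is 0. A cell is
significant when p ≤ alpha (0.05 default). No multiple-testing correction
is applied by default — the table replicates the raw-alpha convention of
the layout it mirrors — but Benjamini–Hochberg adjustment across the 270
cells is available (`fdr=True`). Subjects missing a stage are excluded
from that contrast only (with a warning), never globally. Cells with
fewer than five informative (non-zero) paired differences — possible for
discrete-valued features such as median frequency — are reported as
p = 1, direction "none".

## Calibration and recovery properties

Under a null scenario (identical profiles in all six stages) the pooled
per-cell rejection rate at alpha = 0.05 stays within the 99% binomial
confidence band of 0.05 over 100 replicate cohorts, for each contrast.
Residual deviation above exactly 0.05 is expected: stages contribute
unequal epoch counts, so paired differences of skewed epoch statistics
are not perfectly symmetric, and the exact test's discreteness makes the
attainable level slightly conservative cell by cell. Under the default
scenario, the LoC contrast recovers significant relative-delta increase
and relative-alpha/beta decrease, and the incision contrast recovers the
delta-up/alpha-down signature, on a majority of channels in well over 80%
of replicate cohorts. The intubation effect is a global attenuation and
is recovered through the amplitude-sensitive features (activity, RMS,
wavelet SD/extrema), not through relative band powers, which are
scale-invariant by construction.

## Degenerate inputs and numerical conventions

Constant signals raise zero-variance errors (z-score, Hjorth, ApEn
tolerance). All-outlier segments raise a degenerate-signal error. Epochs
shorter than one second are rejected by the PSD (the 0.5 Hz edge would be
unresolvable); fewer than 50 samples are rejected by ApEn; epochs too
short for five dyadic levels raise a depth error. Tolerances asserted in
tests: DWT reconstruction 1e-8, energy conservation 1e-6 (relative),
ApEn-vs-brute-force 1e-10, periodogram-vs-autocorrelation 1e-9,
relative-power partition 1e-9.

## Problem sizes used in the shipped checks

The automated checks simulate cohorts at the full study conditions
(19 subjects, 9 channels, six stages, 24 epochs/subject/channel): 100
replicate cohorts for the null calibration and 50 for directional
recovery; oracle comparisons for ApEn use N = 200 epochs and the
signed-rank enumeration covers n ≤ 12 over 1000 random samples. These
sizes keep each property estimable (binomial CIs of a few percent) at
desk-scale runtimes.

## Known limitations

* Synthetic validation only — no claim about real patient EEG transfers
  from these tests (see the generator's non-goals above).
* The max-normalised total band power is a relative, not absolute,
  power measure; its direction of change can oppose raw total power when
  the spectrum sharpens.
* The d4 band (8–16 Hz) overlaps but does not equal the alpha band
  definition (8–15 Hz).
* EDF files can be read (via MNE, optional extra) but not written; the
  native interchange format is plain CSV.
* Channels are simulated independently; spatial structure across the
  scalp (and hence any topographic inference) is out of scope.
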