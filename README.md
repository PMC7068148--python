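# qeeg — quantitative EEG analysis of anaesthesia stages

`qeeg` is a pipeline for studying how scalp EEG changes across the events
of general anaesthesia — baseline, induction, loss of consciousness
(LoC), intubation, and surgical incision. It is aimed at
neurophysiological signal-processing researchers who want a reproducible,
testable implementation of the classic quantitative-EEG workflow:

1. **Preprocessing**: zero-phase 0.5–35 Hz Butterworth bandpass, robust
   outlier replacement (median ± 3·1.4826·MAD, nearest-neighbour
   imputation), per-channel z-score, segmentation into 4-s epochs, and
   derivation of the bipolar channels FzCz and CzPz from the seven
   referential 10-20 channels (FP1, FP2, P3, P4, Fz, Cz, Pz).
2. **A 30-feature battery per epoch**: Hjorth activity/mobility/complexity
   (var(x), sqrt(var(Δx)/var(x)), mobility(Δx)/mobility(x)), approximate
   entropy ApEn(m=2, r=0.2·SD), RMS; from the max-normalised periodogram
   the total 0.5–30 Hz power, relative delta/theta/alpha/beta powers
   ([0.5,4), [4,8), [8,15), [15,30) Hz), spectral entropy, median, 95%
   spectral-edge and mean frequency; and mean/SD/max/min of the a5, d5,
   d4, d3 coefficients of a 5-level Daubechies wavelet decomposition.
3. **Paired statistics**: features averaged per subject × channel × stage,
   then two-sided Wilcoxon signed-rank tests (exact enumeration for
   n ≤ 25, midranks for ties, zeros discarded) for three stage contrasts
   — baseline vs LoC, pre vs post intubation, pre vs post incision —
   laid out as 30-feature × 9-channel tables of p-values with direction
   flags at P ≤ 0.05.

Because clinical recordings of this kind are rarely shareable, the
package includes a **synthetic cohort generator**: multichannel,
stage-marked EEG built from band-limited noise whose per-band amplitudes
shift by stage (delta up and alpha/beta down at LoC; global attenuation
at intubation; delta up with alpha down — "paradoxical arousal" — at
incision), with log-normal inter-subject variability. Every downstream
stage is exercised and calibrated against it; see `docs/methods.md` for
the model and its limits.

## Worked example

```sh
qeeg run-all --seed 1 -n 19 -o results_run
```

prints

```
baseline_vs_loc: n_pairs=19, 208/270 significant cells
pre_vs_post_intubation: n_pairs=19, 141/270 significant cells
pre_vs_post_incision: n_pairs=19, 232/270 significant cells
outputs in results_run/
```

and writes, per contrast, `pvalues_<contrast>.csv` (30 features × 9
channels), `direction_<contrast>.csv`, and a human-readable
`table_<contrast>.txt` in which significant cells are starred with their
direction, e.g.

```
baseline_vs_loc  (n_pairs=19, alpha=0.05; * significant, +/- direction of post-pre median change)
                         FP1      FP2       P3  ...
hjorth_activity      0.000*+  0.000*+  0.000*+  ...
hjorth_mobility      0.000*-  0.000*-  0.000*-  ...
approximate_entropy  0.000*-  0.000*-  0.000*-  ...
```

Here the LoC state shows the expected loss-of-consciousness signature on
every channel: relative delta power and signal amplitude (activity) rise,
relative alpha falls, and the signal becomes more regular (approximate
entropy falls). `subject_stage_features.csv` holds the subject-averaged
feature values, `stage_summary.csv` the across-subject median/IQR per
feature × channel × stage, and `manifest.json` the seed, configuration
and library versions that make the run bit-reproducible.

The same analysis is available as a library:

```python
from qeeg import (default_scenario, generate_cohort, derive_bipolar,
                  segment_stages, extract_features, average_stage_features,
                  build_comparison_table, PreprocessConfig)

cohort = generate_cohort(default_scenario(seed=1), n_subjects=19)
epoch_sets = [es for rec in cohort
              for es in segment_stages(derive_bipolar(rec), PreprocessConfig())]
features = average_stage_features(extract_features(epoch_sets))
table = build_comparison_table(features, "baseline_vs_loc")
print(table.p_values.loc["rel_delta_power"])   # one p-value per channel
```

Cohorts can also be written to and read from disk (`qeeg simulate`,
`qeeg preprocess`, `qeeg compare`) as plain CSV — one samples file plus an
events sidecar per subject — and scenario/preprocessing/statistics
settings can be supplied in a single YAML file (`-c config.yaml`).

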