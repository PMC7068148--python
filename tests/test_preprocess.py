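"""Preprocessing chain tests: filtering, outlier imputation, z-score,
montage derivation and stage epoching."""

import numpy as np
import pytest

from qeeg.preprocess import (
    CHANNEL_ORDER,
    DegenerateSignalError,
    FilterLengthError,
    MissingStageError,
    MontageError,
    PreprocessConfig,
    SegmentationError,
    StageEpochSet,
    bandpass,
    derive_bipolar,
    replace_outliers,
    segment_stages,
    zscore,
)
from qeeg.simulate import Recording, default_scenario, generate_subject

CFG = PreprocessConfig()
FS = 256.0


def tone(freq, seconds=8.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def tone_power(x, freq, fs=FS):
    p = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return p[np.argmin(np.abs(f - freq))]


class TestBandpass:
    def test_passband_preserves_10hz_tone(self):
        x = tone(10)
        y = bandpass(x, FS, CFG)
        ratio = np.sqrt(tone_power(y, 10) / tone_power(x, 10))
        assert abs(ratio - 1) < 0.05

    def test_stopband_kills_60hz_tone(self):
        x = tone(60)
        y = bandpass(x, FS, CFG)
        assert tone_power(y, 60) <= 0.01 * tone_power(x, 60)

    def test_50hz_attenuated_20db(self):
        x = tone(50)
        y = bandpass(x, FS, CFG)
        atten_db = 10 * np.log10(tone_power(x, 50) / tone_power(y, 50))
        assert atten_db >= 20

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(bandpass(np.zeros(2048), FS, CFG), 0.0)

    def test_short_signal_errors(self):
        with pytest.raises(FilterLengthError):
            bandpass(np.ones(10), FS, CFG)


class TestReplaceOutliers:
    def test_single_spike_imputed_from_zero_neighbours(self):
        x = np.array([0.0, 0, 0, 100, 0, 0, 0])
        np.testing.assert_array_equal(replace_outliers(x, CFG), np.zeros(7))

    def test_clean_signal_unchanged(self, rng):
        x = rng.standard_normal(512)
        cfg = PreprocessConfig(outlier_k=10)
        np.testing.assert_array_equal(replace_outliers(x, cfg), x)

    def test_mad_rule_flags_all_values_off_the_median(self):
        # with MAD = 0 every sample off the median is flagged, so both 9
        # and 5 are imputed from the surrounding ones
        x = np.array([1.0, 1, 1, 1, 9, 5, 1, 1])
        np.testing.assert_array_equal(replace_outliers(x, CFG), np.ones(8))

    def test_edge_outlier_uses_one_side(self):
        x = np.array([100.0, 0, 0, 0, 0, 0, 0])
        y = replace_outliers(x, CFG)
        assert y[0] == 0.0

    def test_interior_outlier_averages_both_sides(self):
        x = np.array([2.0] * 10 + [50.0] + [4.0] * 10)
        y = replace_outliers(x, CFG)
        assert y[10] == pytest.approx(3.0)

    def test_all_flagged_errors(self):
        cfg = PreprocessConfig(outlier_k=0.1)
        with pytest.raises(DegenerateSignalError):
            replace_outliers(np.arange(8.0), cfg)


class TestZscore:
    def test_closed_form(self):
        np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        z = zscore(rng.standard_normal(1000) * 7 + 3)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_idempotent(self, rng):
        x = rng.standard_normal(256)
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-12)

    def test_constant_errors(self):
        with pytest.raises(DegenerateSignalError):
            zscore(np.full(10, 3.0))


class TestDeriveBipolar:
    def _recording(self, rng, labels=("FP1", "FP2", "P3", "P4", "Fz", "Cz", "Pz")):
        samples = rng.standard_normal((len(labels), 512))
        return Recording("S1", list(labels), FS, samples, [("baseline", 0, 512)])

    def test_output_order_and_values(self, rng):
        rec = self._recording(rng)
        out = derive_bipolar(rec)
        assert out.channel_labels == list(CHANNEL_ORDER)
        i = {lab: k for k, lab in enumerate(rec.channel_labels)}
        np.testing.assert_array_equal(
            out.samples[out.channel_labels.index("FzCz")],
            rec.samples[i["Fz"]] - rec.samples[i["Cz"]],
        )
        np.testing.assert_array_equal(
            out.samples[out.channel_labels.index("CzPz")],
            rec.samples[i["Cz"]] - rec.samples[i["Pz"]],
        )

    def test_identical_sources_give_zero_channel(self, rng):
        rec = self._recording(rng)
        rec.samples[rec.channel_labels.index("Fz")] = rec.samples[
            rec.channel_labels.index("Cz")
        ]
        out = derive_bipolar(rec)
        np.testing.assert_array_equal(
            out.samples[out.channel_labels.index("FzCz")], 0.0
        )

    def test_missing_source_errors(self, rng):
        rec = self._recording(rng, labels=("FP1", "FP2", "P3", "P4", "Fz", "Cz"))
        with pytest.raises(MontageError):
            derive_bipolar(rec)


@pytest.fixture(scope="module")
def epoch_sets():
    rec = generate_subject(default_scenario(seed=2), "S1", np.random.default_rng(2))
    return segment_stages(derive_bipolar(rec), CFG)


class TestSegmentStages:
    def test_counts_by_stage(self, epoch_sets):
        by_stage = {}
        for es in epoch_sets:
            by_stage.setdefault(es.stage_label, set()).add(es.n_epochs)
        assert by_stage["baseline"] == {15}
        assert by_stage["loc"] == {2}
        assert by_stage["incision"] == {1}

    def test_cartesian_product_of_sets(self, epoch_sets):
        assert len(epoch_sets) == 9 * 6
        assert {es.channel_label for es in epoch_sets} == set(CHANNEL_ORDER)

    def test_epoch_length(self, epoch_sets):
        assert all(es.epochs.shape[1] == 1024 for es in epoch_sets)

    def test_missing_event_errors(self, rng):
        rec = Recording(
            "S1",
            list(CHANNEL_ORDER),
            FS,
            rng.standard_normal((9, 4096)),
            [("baseline", 0, 4096)],
        )
        with pytest.raises(MissingStageError):
            segment_stages(rec, CFG)

    def test_short_segment_errors(self, rng):
        events = [("baseline", 0, 512)]  # 2 s < one 4-s epoch
        rec = Recording(
            "S1", list(CHANNEL_ORDER), FS, rng.standard_normal((9, 4096)), events
        )
        cfg = PreprocessConfig(stages=("baseline",))
        with pytest.raises(SegmentationError):
            segment_stages(rec, cfg)

    def test_epochs_tile_the_cleaned_segment(self, rng):
        """Concatenated epochs reproduce the preprocessed segment exactly
        and z-scoring uses one scale across a channel's stages."""
        rec = generate_subject(
            default_scenario(seed=3), "S1", np.random.default_rng(3)
        )
        sets = segment_stages(derive_bipolar(rec), CFG)
        fz_sets = [es for es in sets if es.channel_label == "Fz"]
        pooled = np.concatenate([es.epochs.ravel() for es in fz_sets])
        assert abs(pooled.mean()) < 1e-9
        assert abs(pooled.std(ddof=1) - 1) < 1e-3  # trimming-free tiling
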