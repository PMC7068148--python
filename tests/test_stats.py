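"""Statistics-layer tests: exact signed-rank p-values against exhaustive
sign-pattern enumeration (and scipy as an independent library check),
stage averaging, and comparison-table construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from qeeg.features import FEATURE_ORDER
from qeeg.preprocess import CHANNEL_ORDER
from qeeg.stats import (
    CONTRASTS,
    InsufficientSubjectsError,
    SmallSampleError,
    average_stage_features,
    build_comparison_table,
    stage_summary,
    wilcoxon_signed_rank,
)


def enumerate_signed_rank_p(diffs):
    """Oracle: exhaust all 2^n sign assignments of the ranked |d|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    w_all = signs @ ranks
    lower = np.mean(w_all <= w_obs + 1e-12)
    upper = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_six_positive_pairs_exact_p(self):
        pre = np.zeros(6)
        post = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        p, direction = wilcoxon_signed_rank(pre, post)
        assert p == 0.03125  # 2 / 2^6
        assert direction == "increase"

    def test_identical_pairs_degenerate(self):
        x = np.arange(8.0)
        assert wilcoxon_signed_rank(x, x) == (1.0, "none")

    def test_too_few_nonzero_pairs_error(self):
        pre = np.zeros(6)
        post = np.array([1.0, 2.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(SmallSampleError):
            wilcoxon_signed_rank(pre, post)

    @pytest.mark.parametrize("n", range(5, 13))
    def test_matches_exhaustive_enumeration(self, n, rng):
        for rep in range(25):
            post = rng.standard_normal(n)
            if rep % 3 == 0:  # force ties and zeros
                post = np.round(post * 2) / 2
            pre = np.zeros(n)
            d = post[post != 0]
            if d.size < 5:
                continue
            p, _ = wilcoxon_signed_rank(pre, post)
            assert p == pytest.approx(enumerate_signed_rank_p(post), abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        for _ in range(20):
            pre = rng.standard_normal(10)
            post = pre + rng.standard_normal(10)
            p, _ = wilcoxon_signed_rank(pre, post)
            p_scipy = scipy_wilcoxon(post - pre, method="exact").pvalue
            assert p == pytest.approx(p_scipy, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self, rng):
        for _ in range(10):
            pre = rng.standard_normal(40)
            post = pre + 0.3 + rng.standard_normal(40)
            p, _ = wilcoxon_signed_rank(pre, post)
            p_scipy = scipy_wilcoxon(
                post - pre, method="approx", correction=True
            ).pvalue
            assert p == pytest.approx(p_scipy, rel=1e-6)

    def test_direction_from_median_difference(self):
        pre = np.zeros(7)
        post = np.array([-5.0, -4.0, -3.0, -1.0, 1.0, 2.0, 3.0])
        _, direction = wilcoxon_signed_rank(pre, post)
        assert direction == "decrease"


def make_epoch_frame(values):
    """Small long-format frame: {(subject, channel, stage): [epoch values]}."""
    rows = []
    for (subject, channel, stage), vals in values.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "subject": subject,
                    "channel": channel,
                    "stage": stage,
                    "epoch_index": i,
                    "feature": "rms_value",
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestAveraging:
    def test_mean_over_epochs(self):
        df = make_epoch_frame({("S1", "Fz", "baseline"): [1.0, 2.0, 6.0]})
        out = average_stage_features(df)
        assert out["value"].iloc[0] == pytest.approx(3.0)

    def test_single_epoch_stage_passthrough(self):
        df = make_epoch_frame({("S1", "Fz", "incision"): [4.2]})
        assert average_stage_features(df)["value"].iloc[0] == 4.2

    def test_fifteen_epoch_hand_oracle(self, rng):
        vals = rng.standard_normal(15)
        df = make_epoch_frame({("S1", "Fz", "baseline"): list(vals)})
        assert average_stage_features(df)["value"].iloc[0] == pytest.approx(
            vals.mean()
        )


def synthetic_subject_frame(rng, n_subjects, effect=0.0, stages=("baseline", "loc")):
    """Subject-averaged frame over all features/channels with an additive
    stage effect on the post stage."""
    rows = []
    for s in range(n_subjects):
        base = rng.standard_normal((len(FEATURE_ORDER), len(CHANNEL_ORDER)))
        for si, stage in enumerate(stages):
            vals = base + (effect * si) + 0.2 * rng.standard_normal(base.shape)
            for fi, feat in enumerate(FEATURE_ORDER):
                for ci, ch in enumerate(CHANNEL_ORDER):
                    rows.append(
                        {
                            "subject": f"S{s:02d}",
                            "channel": ch,
                            "stage": stage,
                            "feature": feat,
                            "value": vals[fi, ci],
                        }
                    )
    return pd.DataFrame(rows)


class TestComparisonTable:
    def test_shape_order_and_flags(self, rng):
        df = synthetic_subject_frame(rng, 8, effect=2.0)
        table = build_comparison_table(df, "baseline_vs_loc")
        assert list(table.p_values.index) == list(FEATURE_ORDER)
        assert list(table.p_values.columns) == list(CHANNEL_ORDER)
        assert table.p_values.shape == (30, 9)
        assert table.n_pairs == 8
        np.testing.assert_array_equal(
            table.significant.to_numpy(), (table.p_values <= 0.05).to_numpy()
        )
        assert (table.directions.to_numpy() == "increase").mean() > 0.9

    def test_invariant_to_row_order(self, rng):
        df = synthetic_subject_frame(rng, 7, effect=0.5)
        t1 = build_comparison_table(df, "baseline_vs_loc")
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        t2 = build_comparison_table(shuffled, "baseline_vs_loc")
        pd.testing.assert_frame_equal(t1.p_values, t2.p_values)
        pd.testing.assert_frame_equal(t1.directions, t2.directions)

    def test_subject_missing_stage_is_dropped(self, rng):
        df = synthetic_subject_frame(rng, 7, effect=0.5)
        df = df[~((df["subject"] == "S00") & (df["stage"] == "loc"))]
        with pytest.warns(UserWarning, match="S00"):
            table = build_comparison_table(df, "baseline_vs_loc")
        assert table.n_pairs == 6

    def test_too_few_subjects_errors(self, rng):
        df = synthetic_subject_frame(rng, 4)
        with pytest.raises(InsufficientSubjectsError):
            build_comparison_table(df, "baseline_vs_loc")

    def test_alpha_changes_only_flags(self, rng):
        df = synthetic_subject_frame(rng, 8, effect=0.4)
        t5 = build_comparison_table(df, "baseline_vs_loc", alpha=0.05)
        t1 = build_comparison_table(df, "baseline_vs_loc", alpha=0.01)
        pd.testing.assert_frame_equal(t5.p_values, t1.p_values)
        assert t1.significant.to_numpy().sum() <= t5.significant.to_numpy().sum()

    def test_unknown_contrast_errors(self, rng):
        with pytest.raises(KeyError):
            build_comparison_table(
                synthetic_subject_frame(rng, 6), "baseline_vs_recovery"
            )


def test_stage_summary_medians_and_iqr(rng):
    df = synthetic_subject_frame(rng, 9)
    out = stage_summary(df)
    assert set(out.columns) >= {"channel", "stage", "feature", "median", "iqr"}
    assert len(out) == 2 * len(FEATURE_ORDER) * len(CHANNEL_ORDER)
    row = out.iloc[0]
    vals = df[
        (df["channel"] == row["channel"])
        & (df["stage"] == row["stage"])
        & (df["feature"] == row["feature"])
    ]["value"]
    assert row["median"] == pytest.approx(vals.median())
    assert row["iqr"] == pytest.approx(
        np.percentile(vals, 75) - np.percentile(vals, 25)
    )


def test_contrast_map_covers_tables():
    assert set(CONTRASTS) == {
        "baseline_vs_loc",
        "pre_vs_post_intubation",
        "pre_vs_post_incision",
    }
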