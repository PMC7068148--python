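"""Stage averaging, paired Wilcoxon signed-rank tests, comparison tables.

Per-epoch features are averaged within subject x channel x stage, then
each of the three stage contrasts (baseline vs LoC, pre vs post
intubation, pre vs post incision) is tested per feature x channel with a
two-sided Wilcoxon signed-rank test at alpha = 0.05, yielding a 30 x 9
table of p-values with a direction flag (sign of the median paired
difference, post minus pre).

The signed-rank test is implemented here rather than delegated: zero
differences are discarded (Wilcoxon's original rule), tied absolute
differences get midranks, and for n <= 25 remaining pairs the p-value
comes from exact enumeration of the signed-rank distribution (a
subset-sum convolution over the double-ranks, which are integers even
with midranks).  Above n = 25 a normal approximation with tie and
continuity corrections is used.  No multiple-testing correction is
applied by default, matching the raw-alpha convention of the tables this
layout mirrors; Benjamini-Hochberg adjustment is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .features import FEATURE_ORDER
from .preprocess import CHANNEL_ORDER

__all__ = [
    "CONTRASTS",
    "SubjectStageFeatures",
    "ComparisonTable",
    "average_stage_features",
    "wilcoxon_signed_rank",
    "build_comparison_table",
    "stage_summary",
]

#: contrast name -> (pre stage, post stage)
CONTRASTS = {
    "baseline_vs_loc": ("baseline", "loc"),
    "pre_vs_post_intubation": ("loc", "intubation"),
    "pre_vs_post_incision": ("preincision", "incision"),
}

_EXACT_MAX_N = 25


class SmallSampleError(ValueError):
    """Fewer than 5 non-zero paired differences."""


class InsufficientSubjectsError(ValueError):
    """Fewer than 5 subjects have both stages of the contrast."""


@dataclass
class SubjectStageFeatures:
    """Epoch-averaged 30-feature vector of one subject x channel x stage."""

    subject_id: str
    channel_label: str
    stage_label: str
    features: dict[str, float]


@dataclass
class ComparisonTable:
    """Feature x channel matrix of one stage contrast.

    ``p_values``, ``directions`` and ``significant`` are DataFrames
    indexed by :data:`~qeeg.features.FEATURE_ORDER` with columns in
    :data:`~qeeg.preprocess.CHANNEL_ORDER`.
    """

    contrast: str
    alpha: float
    n_pairs: int
    p_values: pd.DataFrame = field(repr=False)
    directions: pd.DataFrame = field(repr=False)

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_values <= self.alpha

    def to_text(self) -> str:
        """Human-readable table: p-values, significant cells starred with
        their direction (+ increase, - decrease)."""
        mark = {"increase": "+", "decrease": "-", "none": " "}
        cells = self.p_values.copy().astype(object)
        for feat in cells.index:
            for ch in cells.columns:
                p = self.p_values.loc[feat, ch]
                star = (
                    f"*{mark[self.directions.loc[feat, ch]]}"
                    if p <= self.alpha
                    else "  "
                )
                cells.loc[feat, ch] = f"{p:0.3f}{star}"
        header = (
            f"{self.contrast}  (n_pairs={self.n_pairs}, alpha={self.alpha}; "
            "* significant, +/- direction of post-pre median change)\n"
        )
        return header + cells.to_string()


def average_stage_features(epoch_features: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each feature over a stage's epochs.

    Input and output are long-format frames; the output has one row per
    subject x channel x stage x feature.
    """
    grouped = (
        epoch_features.groupby(
            ["subject", "channel", "stage", "feature"], sort=False, observed=True
        )["value"]
        .mean()
        .reset_index()
    )
    return grouped


def _subset_sum_counts(double_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of subset sums of ``double_ranks`` (null distribution of
    2*W+ under uniform sign assignment)."""
    total = int(sum(double_ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.concatenate([np.zeros(r), counts[: total + 1 - r]])
        counts = counts + shifted
    return counts


@lru_cache(maxsize=64)
def _no_tie_counts(n: int) -> np.ndarray:
    # without ties the ranks are always 1..n, so the distribution depends
    # on n alone and is worth caching across the 270 cells of a table
    return _subset_sum_counts(tuple(2 * k for k in range(1, n + 1)))


def _exact_signed_rank_p(double_ranks: np.ndarray, w2_plus: int) -> float:
    """Two-sided exact p by subset-sum enumeration over doubled midranks;
    p = min(1, 2 x smaller tail), tails inclusive of the observed value."""
    n = double_ranks.size
    if np.array_equal(np.sort(double_ranks), 2 * np.arange(1, n + 1)):
        counts = _no_tie_counts(n)
    else:
        counts = _subset_sum_counts(tuple(int(r) for r in double_ranks))
    denom = 2.0**n
    lower = counts[: w2_plus + 1].sum() / denom
    upper = counts[w2_plus:].sum() / denom
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, str]:
    """Two-sided paired signed-rank p-value and direction of change.

    Direction is the sign of the median of (post - pre) over all pairs
    (including zero differences): "increase", "decrease" or "none".
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    d = post - pre
    med = np.median(d)
    direction = "increase" if med > 0 else "decrease" if med < 0 else "none"
    dnz = d[d != 0]
    n = dnz.size
    if n == 0:
        return 1.0, "none"
    if n < 5:
        raise SmallSampleError(f"only {n} non-zero differences (need >= 5)")
    from scipy.stats import norm, rankdata

    ranks = rankdata(np.abs(dnz))  # midranks for ties
    w_plus = ranks[dnz > 0].sum()
    if n <= _EXACT_MAX_N:
        double_ranks = np.rint(2.0 * ranks).astype(np.int64)
        w2 = int(np.rint(2.0 * w_plus))
        p = _exact_signed_rank_p(double_ranks, w2)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        delta = w_plus - mean
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return float(p), direction


def build_comparison_table(
    features: pd.DataFrame | list[SubjectStageFeatures],
    contrast: str,
    alpha: float = 0.05,
    fdr: bool = False,
) -> ComparisonTable:
    """30 x 9 Wilcoxon table for one stage contrast.

    ``features`` is the subject-averaged long frame from
    :func:`average_stage_features` (or a list of
    :class:`SubjectStageFeatures`).  Subjects missing either stage of the
    contrast are dropped from this contrast only, with a warning.  With
    ``fdr=True`` the significance threshold is Benjamini-Hochberg adjusted
    across the 270 cells (p-values themselves are reported raw).
    """
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}")
    pre_stage, post_stage = CONTRASTS[contrast]
    df = _as_long_frame(features)
    sub = df[df["stage"].isin([pre_stage, post_stage])]
    wide = sub.pivot_table(
        index="subject",
        columns=["stage", "feature", "channel"],
        values="value",
        observed=True,
    )
    have_pre = wide.get(pre_stage)
    have_post = wide.get(post_stage)
    if have_pre is None or have_post is None:
        raise InsufficientSubjectsError(
            f"no data for one stage of contrast {contrast!r}"
        )
    complete = wide.dropna().index
    dropped = sorted(set(wide.index) - set(complete))
    if dropped:
        warnings.warn(
            f"{contrast}: excluding subjects missing a stage: {dropped}",
            stacklevel=2,
        )
    n_pairs = len(complete)
    if n_pairs < 5:
        raise InsufficientSubjectsError(
            f"{contrast}: only {n_pairs} subjects have both stages (need >= 5)"
        )
    # materialise as (subject, feature x channel) arrays for the cell loop
    cell_cols = pd.MultiIndex.from_product(
        [list(FEATURE_ORDER), list(CHANNEL_ORDER)], names=["feature", "channel"]
    )
    pre_arr = wide.loc[complete, pre_stage].reindex(columns=cell_cols).to_numpy()
    post_arr = wide.loc[complete, post_stage].reindex(columns=cell_cols).to_numpy()
    n_feat, n_chan = len(FEATURE_ORDER), len(CHANNEL_ORDER)
    p_mat = np.empty((n_feat, n_chan))
    dir_mat = np.empty((n_feat, n_chan), dtype=object)
    for fi in range(n_feat):
        for ci in range(n_chan):
            col = fi * n_chan + ci
            try:
                cell = wilcoxon_signed_rank(pre_arr[:, col], post_arr[:, col])
            except SmallSampleError:
                # discrete-valued features (e.g. median frequency) can tie
                # across stages; with < 5 informative pairs the cell is
                # untestable and reported as non-significant
                cell = (1.0, "none")
            p_mat[fi, ci], dir_mat[fi, ci] = cell
    p = pd.DataFrame(p_mat, index=list(FEATURE_ORDER), columns=list(CHANNEL_ORDER))
    direction = pd.DataFrame(
        dir_mat, index=list(FEATURE_ORDER), columns=list(CHANNEL_ORDER)
    )
    eff_alpha = alpha
    if fdr:
        from scipy.stats import false_discovery_control

        flat = p.to_numpy().ravel()
        adjusted = false_discovery_control(flat, method="bh")
        rejected = adjusted <= alpha
        eff_alpha = flat[rejected].max() if rejected.any() else 0.0
    return ComparisonTable(
        contrast=contrast,
        alpha=float(eff_alpha),
        n_pairs=n_pairs,
        p_values=p,
        directions=direction,
    )


def stage_summary(features: pd.DataFrame | list[SubjectStageFeatures]) -> pd.DataFrame:
    """Across-subject median and interquartile range per
    feature x channel x stage (the numeric content of per-channel
    box summaries of the stage axis)."""
    df = _as_long_frame(features)
    g = df.groupby(["channel", "stage", "feature"], sort=False, observed=True)["value"]
    out = g.agg(
        median="median",
        q1=lambda v: float(np.percentile(v, 25)),
        q3=lambda v: float(np.percentile(v, 75)),
        n_subjects="count",
    ).reset_index()
    out["iqr"] = out["q3"] - out["q1"]
    return out


def _as_long_frame(
    features: pd.DataFrame | list[SubjectStageFeatures],
) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    rows = [
        {
            "subject": f.subject_id,
            "channel": f.channel_label,
            "stage": f.stage_label,
            "feature": name,
            "value": value,
        }
        for f in features
        for name, value in f.features.items()
    ]
    return pd.DataFrame(rows)
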