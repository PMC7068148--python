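"""End-to-end orchestration: simulate/load -> preprocess -> features ->
stage averages -> comparison tables -> output bundle.

A run is described by a :class:`RunConfig` (buildable from a YAML file);
its output directory receives, deterministically for a given config:

* ``pvalues_<contrast>.csv`` / ``direction_<contrast>.csv`` /
  ``table_<contrast>.txt`` for each of the three contrasts;
* ``subject_stage_features.csv`` (subject-averaged long format);
* ``stage_summary.csv`` (across-subject median/IQR per
  feature x channel x stage);
* ``manifest.json`` recording seed, configuration and library versions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_features
from .preprocess import PreprocessConfig, derive_bipolar, segment_stages
from .simulate import (
    BandProfile,
    Recording,
    StageScenario,
    default_scenario,
    generate_cohort,
)
from .stats import (
    CONTRASTS,
    ComparisonTable,
    average_stage_features,
    build_comparison_table,
    stage_summary,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "load_config", "cohort_tables"]


@dataclass
class RunConfig:
    scenario: StageScenario = field(default_factory=default_scenario)
    n_subjects: int = 19
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    alpha: float = 0.05
    fdr: bool = False
    contrasts: tuple[str, ...] = tuple(CONTRASTS)
    output_dir: str = "qeeg_output"


@dataclass
class RunResult:
    tables: dict[str, ComparisonTable]
    subject_features: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict


def _scenario_from_dict(d: dict) -> StageScenario:
    kwargs = dict(d)
    profiles = kwargs.pop("stage_profiles", None)
    base = default_scenario()
    if profiles is not None:
        parsed = {}
        for stage, p in profiles.items():
            parsed[stage] = BandProfile(
                delta_amp=float(p["delta_amp"]),
                theta_amp=float(p["theta_amp"]),
                alpha_amp=float(p["alpha_amp"]),
                beta_amp=float(p["beta_amp"]),
                pink_floor=float(p.get("pink_floor", 0.0)),
            )
        stage_profiles = parsed
    else:
        stage_profiles = base.stage_profiles
    if "stage_durations" in kwargs:
        kwargs["stage_durations"] = {
            k: float(v) for k, v in kwargs["stage_durations"].items()
        }
    if "channels" in kwargs:
        kwargs["channels"] = tuple(kwargs["channels"])
    return dataclasses.replace(base, stage_profiles=stage_profiles, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file; every section and key
    is optional and overlays the defaults."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "scenario" in raw:
        cfg.scenario = _scenario_from_dict(raw["scenario"])
    if "preprocess" in raw:
        cfg.preprocess = PreprocessConfig(**raw["preprocess"])
    if "features" in raw:
        cfg.features = FeatureConfig(**raw["features"])
    for key in ("n_subjects", "alpha", "fdr", "output_dir"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "contrasts" in raw:
        cfg.contrasts = tuple(raw["contrasts"])
    return cfg


def cohort_features(
    recordings: list[Recording],
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Subject-averaged long feature frame for a list of recordings."""
    epoch_sets = []
    for rec in recordings:
        epoch_sets.extend(segment_stages(derive_bipolar(rec), preprocess_cfg))
    per_epoch = extract_features(epoch_sets, feature_cfg)
    return average_stage_features(per_epoch)


def cohort_tables(
    recordings: list[Recording],
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
    alpha: float = 0.05,
    fdr: bool = False,
    contrasts: tuple[str, ...] = tuple(CONTRASTS),
) -> tuple[dict[str, ComparisonTable], pd.DataFrame]:
    """Comparison tables (and the averaged features) for a cohort."""
    averaged = cohort_features(recordings, preprocess_cfg, feature_cfg)
    tables = {
        c: build_comparison_table(averaged, c, alpha=alpha, fdr=fdr)
        for c in contrasts
    }
    return tables, averaged


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis and write the output bundle.

    The cohort is simulated from ``config.scenario`` (to analyse existing
    recordings, use :func:`cohort_tables` directly).  Output is
    bit-reproducible for a fixed config.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = generate_cohort(config.scenario, config.n_subjects)
    tables, averaged = cohort_tables(
        recordings,
        config.preprocess,
        config.features,
        alpha=config.alpha,
        fdr=config.fdr,
        contrasts=config.contrasts,
    )
    summary = stage_summary(averaged)

    averaged.to_csv(out_dir / "subject_stage_features.csv", index=False)
    summary.to_csv(out_dir / "stage_summary.csv", index=False)
    for name, table in tables.items():
        table.p_values.to_csv(out_dir / f"pvalues_{name}.csv", float_format="%.6g")
        table.directions.to_csv(out_dir / f"direction_{name}.csv")
        (out_dir / f"table_{name}.txt").write_text(table.to_text() + "\n")

    manifest = _manifest(config)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(
        tables=tables, subject_features=averaged, summary=summary, manifest=manifest
    )


def _manifest(config: RunConfig) -> dict:
    import pywt
    import scipy

    from . import __version__

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj

    config = plain(config)
    config.pop("output_dir", None)  # the science config, not the run location
    return {
        "seed": config["scenario"]["seed"],
        "n_subjects": config["n_subjects"],
        "config": config,
        "versions": {
            "qeeg": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "pywavelets": pywt.__version__,
        },
    }
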