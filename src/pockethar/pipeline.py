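"""End-to-end orchestration with reproducible configuration and caching.

Stages: simulate -> preprocess -> features (incl. selection) -> sweep ->
report.  Each stage writes its artifacts plus a ``manifest.json`` holding
the hash of the configuration slice it depends on (chained through the
upstream stage's hash); re-running with an unchanged configuration skips
the stage.  Everything is deterministic under ``RunConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .activities import ACTIVITIES
from .evaluation import SweepReport, sweep_window_lengths
from .features import (
    FEATURE_NAMES,
    FeatureMatrix,
    extract_features,
    read_features_csv,
    select_top_features,
    write_features_csv,
)
from .preprocess import read_uniform_csv, resample_fixed, write_uniform_csv
from .synthetic import make_protocol, read_recording_csv, simulate_cohort, write_cohort_csv
from .windowing import bookkeeping_table

__all__ = [
    "ConfigError", "DataError", "StageError", "RunConfig",
    "run_simulate", "run_preprocess", "run_features", "run_sweep", "run_full",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(range(5, 196, 10))


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or missing data (CLI exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 4)."""


_PROFILES = {
    # profile-dependent defaults, overridable field by field
    "paper": {"epochs": 500, "batch_size": 2000, "learning_rate": 0.001,
              "duration_scale": 1.0, "cohort_size": 42},
    "desk": {"epochs": 10, "batch_size": 256, "learning_rate": 0.003,
             "duration_scale": 0.02, "cohort_size": 8},
}


@dataclass
class RunConfig:
    """Declarative description of one full pipeline run."""

    seed: int = 0
    model_profile: str = "desk"
    cohort_size: int | None = None
    rate_hz: float = 30.0
    window_grid: tuple[int, ...] = ()
    stride: int = 1
    selected_features: "str | tuple" = "auto"
    n_selected: int = 4
    checkpoint_policy: str = "last"
    output_dir: str = "runs/out"
    duration_scale: float | None = None
    missing_fraction: float = 0.05
    noise_sd: float = 0.1
    epochs: int | None = None
    batch_size: int | None = None
    learning_rate: float | None = None

    def __post_init__(self) -> None:
        if self.model_profile not in _PROFILES:
            raise ConfigError(f"model_profile must be one of {sorted(_PROFILES)}")
        prof = _PROFILES[self.model_profile]
        for name in ("cohort_size", "duration_scale", "epochs", "batch_size",
                     "learning_rate"):
            if getattr(self, name) is None:
                setattr(self, name, prof[name])
        if not self.window_grid:
            self.window_grid = DEFAULT_GRID if self.model_profile == "paper" else (5, 35, 55)
        self.window_grid = tuple(int(w) for w in self.window_grid)
        if self.cohort_size < 2:
            raise ConfigError("cohort_size must be >= 2 (leave-one-subject-out)")
        if min(self.window_grid) < 1 or self.stride < 1:
            raise ConfigError("window lengths and stride must be >= 1")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigError("missing_fraction must lie in [0, 1)")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_grid"] = list(self.window_grid)
        if not isinstance(self.selected_features, str):
            d["selected_features"] = list(self.selected_features)
        return d


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_fresh(stage_dir: Path, stage_hash: str) -> bool:
    manifest = stage_dir / "manifest.json"
    if not manifest.exists():
        return False
    try:
        return json.loads(manifest.read_text()).get("hash") == stage_hash
    except json.JSONDecodeError:
        return False


def _write_manifest(stage_dir: Path, stage_hash: str, payload: dict) -> None:
    payload = {"hash": stage_hash, "version": __version__, **payload}
    (stage_dir / "manifest.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: RunConfig) -> tuple[Path, str]:
    """Simulate the cohort and write per-participant CSVs + manifest."""
    stage_dir = Path(config.output_dir) / "cohort"
    relevant = {
        "seed": config.seed, "cohort_size": config.cohort_size,
        "duration_scale": config.duration_scale,
        "missing_fraction": config.missing_fraction, "noise_sd": config.noise_sd,
    }
    stage_hash = _hash(relevant)
    if _stage_fresh(stage_dir, stage_hash):
        logger.info("simulate: cache hit, skipping")
        return stage_dir, stage_hash
    logger.info("simulate: generating %d participants", config.cohort_size)
    stage_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(
        n_participants=config.cohort_size,
        seed=config.seed,
        duration_scale=config.duration_scale,
        missing_fraction=config.missing_fraction,
        noise_sd=config.noise_sd,
    )
    paths = write_cohort_csv(cohort, stage_dir, per_participant=True)
    counts = {
        str(rec.participant_id): {
            a: int(np.sum(rec.labels == a)) for a in ACTIVITIES
        }
        for rec in cohort
    }
    _write_manifest(stage_dir, stage_hash, {
        "params": relevant,
        "protocol_minutes": make_protocol().total_minutes * config.duration_scale,
        "files": [p.name for p in paths],
        "samples_per_activity": counts,
    })
    return stage_dir, stage_hash


def run_preprocess(config: RunConfig, upstream_hash: str) -> tuple[Path, str]:
    """Resample every recording to the uniform rate; write CSVs + manifest."""
    stage_dir = Path(config.output_dir) / "uniform"
    stage_hash = _hash({"upstream": upstream_hash, "rate_hz": config.rate_hz})
    if _stage_fresh(stage_dir, stage_hash):
        logger.info("preprocess: cache hit, skipping")
        return stage_dir, stage_hash
    cohort_dir = Path(config.output_dir) / "cohort"
    csvs = sorted(cohort_dir.glob("participant_*.csv"))
    if not csvs:
        raise DataError(f"no cohort CSVs under {cohort_dir}")
    logger.info("preprocess: resampling %d recordings to %g Hz", len(csvs), config.rate_hz)
    stage_dir.mkdir(parents=True, exist_ok=True)
    uniforms = []
    for path in csvs:
        for rec in read_recording_csv(path):
            uniforms.append(resample_fixed(rec, config.rate_hz))
    write_uniform_csv(uniforms, stage_dir)
    _write_manifest(stage_dir, stage_hash, {
        "rate_hz": config.rate_hz,
        "ticks": {str(u.participant_id): len(u) for u in uniforms},
    })
    return stage_dir, stage_hash


def run_features(config: RunConfig, upstream_hash: str) -> tuple[Path, str]:
    """Extract the nine features, run impurity-based selection, write CSVs."""
    stage_dir = Path(config.output_dir) / "features"
    relevant = {
        "upstream": upstream_hash,
        "selected_features": config.selected_features
        if isinstance(config.selected_features, str)
        else list(config.selected_features),
        "n_selected": config.n_selected,
        "seed": config.seed,
    }
    stage_hash = _hash(relevant)
    if _stage_fresh(stage_dir, stage_hash):
        logger.info("features: cache hit, skipping")
        return stage_dir, stage_hash
    uniform_dir = Path(config.output_dir) / "uniform"
    csvs = sorted(uniform_dir.glob("uniform_*.csv"))
    if not csvs:
        raise DataError(f"no uniform CSVs under {uniform_dir}")
    logger.info("features: extracting w1..w9 for %d participants", len(csvs))
    stage_dir.mkdir(parents=True, exist_ok=True)
    mats = [extract_features(read_uniform_csv(p)) for p in csvs]
    for fm in mats:
        write_features_csv(fm, stage_dir / f"features_{fm.participant_id:02d}.csv")
    if config.selected_features == "auto":
        X = np.concatenate([fm.values for fm in mats])
        y = np.concatenate([fm.labels for fm in mats])
        selected = select_top_features(X, y, k=config.n_selected,
                                       random_state=config.seed)
    else:
        name_to_idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
        try:
            selected = [
                name_to_idx[s] if isinstance(s, str) else int(s)
                for s in config.selected_features
            ]
        except KeyError as exc:
            raise ConfigError(f"unknown feature name {exc}") from exc
    trial_rows = {
        str(fm.participant_id): [
            int(np.sum(fm.trial_ids == t)) for t in np.unique(fm.trial_ids)
        ]
        for fm in mats
    }
    _write_manifest(stage_dir, stage_hash, {
        "selected_indices": list(selected),
        "selected_names": [FEATURE_NAMES[i] for i in selected],
        "trial_rows": trial_rows,
    })
    return stage_dir, stage_hash


def load_feature_stage(config: RunConfig) -> tuple[list[FeatureMatrix], list[int]]:
    stage_dir = Path(config.output_dir) / "features"
    csvs = sorted(stage_dir.glob("features_*.csv"))
    if not csvs:
        raise DataError(f"no feature CSVs under {stage_dir}")
    manifest = json.loads((stage_dir / "manifest.json").read_text())
    return [read_features_csv(p) for p in csvs], list(manifest["selected_indices"])


def run_sweep(config: RunConfig, upstream_hash: str) -> tuple[Path, str]:
    """Run the LOSO window-length sweep on the selected features."""
    stage_dir = Path(config.output_dir) / "sweep"
    relevant = {
        "upstream": upstream_hash, "window_grid": list(config.window_grid),
        "stride": config.stride, "profile": config.model_profile,
        "epochs": config.epochs, "batch_size": config.batch_size,
        "learning_rate": config.learning_rate, "seed": config.seed,
        "checkpoint_policy": config.checkpoint_policy,
    }
    stage_hash = _hash(relevant)
    if _stage_fresh(stage_dir, stage_hash):
        logger.info("sweep: cache hit, skipping")
        return stage_dir, stage_hash
    mats, selected = load_feature_stage(config)
    logger.info("sweep: %d participants, grid %s", len(mats), list(config.window_grid))
    stage_dir.mkdir(parents=True, exist_ok=True)
    report = sweep_window_lengths(
        [fm.select(selected) for fm in mats],
        config.window_grid,
        seed=config.seed,
        estimator_params={
            "architecture": "paper" if config.model_profile == "paper" else "desk",
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "checkpoint_policy": config.checkpoint_policy,
        },
        stride=config.stride,
    )
    report.save(stage_dir)
    feat_manifest = json.loads(
        (Path(config.output_dir) / "features" / "manifest.json").read_text()
    )
    trial_rows = {int(k): v for k, v in feat_manifest["trial_rows"].items()}
    bookkeeping_table(trial_rows, config.window_grid, config.stride).to_csv(
        stage_dir / "bookkeeping.csv", index=False
    )
    _write_manifest(stage_dir, stage_hash, {"params": relevant})
    return stage_dir, stage_hash


def run_full(config: RunConfig, make_plots: bool = True) -> SweepReport:
    """simulate -> preprocess -> features -> sweep (-> figures)."""
    stages = (
        ("simulate", lambda h: run_simulate(config)),
        ("preprocess", lambda h: run_preprocess(config, h)),
        ("features", lambda h: run_features(config, h)),
        ("sweep", lambda h: run_sweep(config, h)),
    )
    h = ""
    for name, fn in stages:
        try:
            _, h = fn(h)
        except (ConfigError, DataError):
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    import pandas as pd

    sweep_dir = Path(config.output_dir) / "sweep"
    tidy = pd.read_csv(sweep_dir / "sweep_tidy.csv")
    acc = tidy[(tidy["metric"] == "accuracy") & (tidy["participant"] >= 0)]
    acc = acc.rename(columns={"value": "accuracy"})[
        ["participant", "window_length", "accuracy"]
    ]
    act = tidy[tidy["participant"] < 0].pivot_table(
        index=["window_length", "activity"], columns="metric", values="value"
    ).reset_index()
    summary = (
        acc.groupby("window_length")["accuracy"]
        .agg(mean_accuracy="mean", sd_accuracy="std")
        .reset_index()
        .fillna({"sd_accuracy": 0.0})
    )
    report = SweepReport(accuracy=acc, activity=act, summary=summary)
    if make_plots:
        from .plots import plot_all

        plot_all(report, sweep_dir / "figures")
    (Path(config.output_dir) / "run_config.json").write_text(
        json.dumps(config.to_dict(), indent=2)
    )
    return report
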