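"""End-to-end run orchestration and file artifacts.

A :class:`RunConfig` describes one reproducible run: where the segments
come from (a synthetic-generation block or CSV paths), how they are
windowed, augmented, filtered and reduced to features, which models are
trained and how they are fused, and the root seed.  ``run_pipeline``
executes ingest -> augment (train-only, inside LOSOCV) -> filter -> IFS
-> FFS -> prune/rank/(select) -> train -> fuse -> LOSOCV report, writing
every artifact with the config snapshot and hash so downstream stages
can refuse stale inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cnn import SCNNConfig
from .datamodel import SegmentSet
from .features import FilterSettings, build_feature_table
from .io import (impute_missing, merge_labels, normalize_and_sort,
                 read_label_csv, read_sensor_csv, window_segments,
                 write_segments)
from .models import EnsembleWeights, EvalReport, LosocvConfig, losocv
from .selection import correlation_prune, importance_rank
from .synthetic import GeneratorConfig, generate_dataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    target: str = "activity"
    dialect: str = "ds2"
    sensor_csv: str | None = None
    label_csv: str | None = None
    simulate: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    sampling_rate: float = 60.0
    window: int = 60
    stride: int = 60
    drop_short: bool = False
    augment_types: tuple | None = None
    augment_factor: float = 3.0
    selection_enabled: bool = False
    correlation_threshold: float = 0.9
    selection_epsilon: float = 0.005
    median_window: int = 5
    cutoff_hz: float = 20.0
    butter_order: int = 3
    scnn_enabled: bool = True
    scnn_max_epochs: int = 500
    scnn_patience: int = 100
    beta_scnn: float = 2.0
    beta_rnf: float = 1.0
    rf_estimators: int = 500
    seed: int = 0
    out_dir: str = "runs/default"

    def __post_init__(self):
        if self.target not in ("activity", "user"):
            raise ValueError("target must be 'activity' or 'user'")
        if self.dialect not in ("ds1", "ds2"):
            raise ValueError("dialect must be 'ds1' or 'ds2'")
        if self.simulate is None and (self.sensor_csv is None
                                      or self.label_csv is None):
            raise ValueError("either a simulate block or sensor+label CSVs "
                             "must be given")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    def config_hash(self) -> str:
        return sha256_of(json.dumps(self.as_dict(), sort_keys=True, default=list))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", "default")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if sim is None:
            raw["simulate"] = None
        elif sim == "default":
            pass  # keep dataclass default
        else:
            if "segment_length_range" in sim:
                sim["segment_length_range"] = tuple(sim["segment_length_range"])
            if sim.get("segments_per_class") is not None:
                sim["segments_per_class"] = tuple(sim["segments_per_class"])
            raw["simulate"] = GeneratorConfig(**sim)
        if raw.get("augment_types") is not None:
            raw["augment_types"] = tuple(
                tuple(t) if isinstance(t, (list, tuple)) else (t,)
                for t in raw["augment_types"])
        return cls(**raw)

    def losocv_config(self) -> LosocvConfig:
        return LosocvConfig(
            target=self.target,
            filter_settings=FilterSettings(self.median_window, self.cutoff_hz,
                                           self.butter_order),
            augment_types=self.augment_types,
            augment_factor=self.augment_factor,
            selection_enabled=self.selection_enabled,
            correlation_threshold=self.correlation_threshold,
            selection_epsilon=self.selection_epsilon,
            scnn=SCNNConfig(max_epochs=self.scnn_max_epochs,
                            patience=self.scnn_patience)
            if self.scnn_enabled else None,
            scnn_input_len=self.window,
            rf_estimators=self.rf_estimators,
            betas=EnsembleWeights(scnn=self.beta_scnn, rnf=self.beta_rnf),
            seed=self.seed)


def sha256_of(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def file_hash(path: str) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:16]


def write_sidecar(artifact_path: str, config_hash: str,
                  upstream: dict[str, str] | None = None,
                  extra: dict | None = None) -> None:
    """Record provenance next to an artifact (config hash + input hashes)."""
    meta = {"config_hash": config_hash, "upstream": upstream or {}}
    if extra:
        meta.update(extra)
    with open(artifact_path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def check_sidecar(artifact_path: str, upstream_paths: dict[str, str]) -> None:
    """Refuse to consume an artifact whose recorded inputs changed."""
    meta_path = artifact_path + ".meta.json"
    if not os.path.exists(meta_path):
        return
    with open(meta_path) as fh:
        meta = json.load(fh)
    for name, path in upstream_paths.items():
        recorded = meta.get("upstream", {}).get(name)
        if recorded is not None and recorded != file_hash(path):
            raise RuntimeError(
                f"stale artifact {artifact_path}: upstream {name!r} changed "
                f"since it was produced (hash mismatch); regenerate it")


def ingest(config: RunConfig) -> SegmentSet:
    """Produce the windowed, labeled SegmentSet a run starts from."""
    if config.simulate is not None:
        segset = generate_dataset(config.simulate)
        fs = config.simulate.sampling_rate
    else:
        samples = read_sensor_csv(config.sensor_csv, config.dialect)
        samples = normalize_and_sort(samples, config.dialect)
        samples = impute_missing(samples)
        labels = read_label_csv(config.label_csv, config.dialect)
        fs = config.sampling_rate
        segset, summary = merge_labels(samples, labels, config.dialect, fs)
        log.info("ingest: %s", summary.as_dict())
    windowed, wsummary = window_segments(segset, config.window, config.stride,
                                         config.drop_short)
    log.info("windowing: %s", wsummary.as_dict())
    return windowed


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute the full run and write its artifacts under ``out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()
    log.info("run %s: root seed %d", chash, config.seed)
    with open(os.path.join(config.out_dir, "config.json"), "w") as fh:
        json.dump(config.as_dict(), fh, indent=2, sort_keys=True, default=list)

    segset = ingest(config)
    seg_path = os.path.join(config.out_dir, "segments.csv")
    write_segments(segset, seg_path,
                   os.path.join(config.out_dir, "manifest.json"),
                   dialect=config.dialect, extra={"config_hash": chash})

    # descriptive full-set artifacts (fold-local fits happen inside losocv)
    settings = FilterSettings(config.median_window, config.cutoff_hz,
                              config.butter_order)
    table = build_feature_table(segset, settings)
    feat_path = os.path.join(config.out_dir, "features.csv")
    table.to_csv(feat_path, index=False)
    write_sidecar(feat_path, chash, {"segments": file_hash(seg_path)})
    pruned, plog, zvar = correlation_prune(table, config.correlation_threshold)
    ranked = importance_rank(pruned, config.target, forest_seed=config.seed,
                             n_estimators=min(config.rf_estimators, 200),
                             prune_log=plog, zero_variance=zvar)
    pd.DataFrame({"name": ranked.names, "score": ranked.scores,
                  "rank": np.arange(1, len(ranked.names) + 1)}
                 ).to_csv(os.path.join(config.out_dir, "ranking.csv"),
                          index=False)

    report = losocv(segset, config.losocv_config())
    metrics_path = os.path.join(config.out_dir, "metrics.json")
    with open(metrics_path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
    pd.DataFrame(report.confusion, index=report.classes,
                 columns=report.classes).to_csv(
        os.path.join(config.out_dir, "confusion.csv"))
    write_sidecar(metrics_path, chash, {"segments": file_hash(seg_path)})
    return report
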