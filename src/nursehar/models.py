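"""Random forest + stacked CNN ensemble and the LOSOCV harness.

The classical branch is a random forest over the 117 statistical
features; the deep branch is the multi-branch CNN over raw acceleration
and angle channels.  Their class-probability outputs are fused by a
beta-weighted sum (default beta = 2 for the CNN, 1 for the forest) and
the argmax of the fused score is the prediction.

Evaluation is leave-one-subject-out cross-validation: one fold per user,
with augmentation, imputation statistics, feature selection and model
fitting confined to the training users of each fold.  Every fold carries
a provenance record so the absence of leakage can be asserted, not
assumed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .augment import AugmentationPlan, balance_augment, default_params
from .cnn import SCNNConfig, build_scnn
from .datamodel import Segment, SegmentSet
from .features import (FilterSettings, build_feature_table, compute_angles,
                       feature_columns, filter_segment)
from .selection import correlation_prune, importance_rank, saturation_select

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleWeights:
    """Fusion weights: fused score S(y) = sum_i beta_i * P_i(y)."""

    scnn: float = 2.0
    rnf: float = 1.0

    def __post_init__(self):
        if self.scnn < 0 or self.rnf < 0:
            raise ValueError("beta weights must be non-negative")
        if self.scnn == 0 and self.rnf == 0:
            raise ValueError("at least one beta must be positive")


@dataclass
class FoldProvenance:
    """Which segments fed which fitted statistic in one LOSOCV fold."""

    held_out_user: str
    test_uids: set = field(default_factory=set)
    train_uids: set = field(default_factory=set)
    augmentation_pool_uids: set = field(default_factory=set)
    imputation_uids: set = field(default_factory=set)
    selection_uids: set = field(default_factory=set)
    model_training_uids: set = field(default_factory=set)


@dataclass
class EvalReport:
    """Per-fold and aggregate LOSOCV metrics (percent) + pooled confusion."""

    classes: list[str]
    fold_users: list[str] = field(default_factory=list)
    per_fold: list[dict] = field(default_factory=list)
    accuracy: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    confusion: np.ndarray | None = None
    per_class_recall: dict = field(default_factory=dict)
    provenance: list[FoldProvenance] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "classes": self.classes,
            "fold_users": self.fold_users,
            "per_fold": self.per_fold,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "per_class_recall": self.per_class_recall,
        }


def compute_metrics(y_true, y_pred, classes: list[str]) -> dict:
    """Accuracy plus macro precision/recall/F1 (percent) and confusion."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("cannot compute metrics on empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    acc = float(np.mean(y_true == y_pred))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return {"accuracy": 100 * acc, "precision": 100 * float(prec),
            "recall": 100 * float(rec), "f1": 100 * float(f1),
            "confusion": cm}


def fuse(probs: list[np.ndarray], betas: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-probability decision fusion.

    Returns (predicted class indices, fused score matrix).  Ties break to
    the lowest class index (argmax convention) and are logged.
    """
    if len(probs) != len(betas):
        raise ValueError("one beta per probability matrix required")
    shape = probs[0].shape
    for p in probs[1:]:
        if p.shape != shape:
            raise ValueError("probability matrices must be congruent")
    fused = sum(b * p for b, p in zip(betas, probs))
    top = np.sort(fused, axis=1)
    ties = np.isclose(top[:, -1], top[:, -2])
    if ties.any():
        log.info("fuse: %d tied fused scores broken to the lowest class index",
                 int(ties.sum()))
    return fused.argmax(axis=1), fused


class RandomForestModel:
    """Random forest over feature tables with a canonical class order."""

    def __init__(self, classes: list[str], n_estimators: int = 500,
                 seed: int = 0, **rf_kwargs):
        self.classes = list(classes)
        self.forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, **rf_kwargs)
        self.features: list[str] | None = None

    def fit(self, table: pd.DataFrame, target: str = "activity",
            features: list[str] | None = None) -> "RandomForestModel":
        label = "activity_id" if target == "activity" else "user_id"
        self.features = features if features is not None else feature_columns(table)
        self.forest.fit(table[self.features].to_numpy(dtype=float),
                        table[label].to_numpy())
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        raw = self.forest.predict_proba(table[self.features].to_numpy(dtype=float))
        out = np.zeros((len(table), len(self.classes)))
        for j, cls in enumerate(self.forest.classes_):
            if cls not in self.classes:
                raise ValueError(f"model class {cls!r} missing from canonical order")
            out[:, self.classes.index(cls)] = raw[:, j]
        return out


CNN_CHANNELS = ("ax", "ay", "az", "angle_x", "angle_y", "angle_z")


def channel_tensor(segset: SegmentSet, length: int,
                   channels: tuple[str, ...] = CNN_CHANNELS,
                   settings: FilterSettings = FilterSettings(),
                   prefiltered: bool = False) -> np.ndarray:
    """Fixed-length per-channel tensor (N, length, n_channels) for the CNN.

    Channels are drawn from the filtered acceleration axes and the
    orientation angles computed from them.  Segments longer than
    ``length`` are truncated; shorter ones are padded by edge
    replication.
    """
    out = np.empty((len(segset), length, len(channels)))
    for i, seg in enumerate(segset):
        f = seg if prefiltered else filter_segment(seg, settings)
        acc = f.samples
        ang = compute_angles(acc)
        cols = {"ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2],
                "angle_x": ang[:, 0], "angle_y": ang[:, 1], "angle_z": ang[:, 2]}
        for c, name in enumerate(channels):
            x = cols[name]
            if len(x) >= length:
                out[i, :, c] = x[:length]
            else:
                out[i, :, c] = np.concatenate(
                    [x, np.full(length - len(x), x[-1])])
    return out


@dataclass(frozen=True)
class LosocvConfig:
    """End-to-end per-fold pipeline settings for LOSOCV."""

    target: str = "activity"
    filter_settings: FilterSettings = FilterSettings()
    # augmentation (training folds only); None disables
    augment_types: tuple | None = None
    augment_factor: float = 3.0
    augment_params: dict | None = None
    # feature selection (training folds only)
    selection_enabled: bool = False
    correlation_threshold: float = 0.9
    selection_epsilon: float = 0.005
    # models
    scnn: SCNNConfig | None = SCNNConfig()
    scnn_input_len: int = 60
    rf_estimators: int = 500
    betas: EnsembleWeights = EnsembleWeights()
    seed: int = 0


def _fold_seed(base: int, fold: int, stream: int) -> int:
    return int(np.random.SeedSequence(
        entropy=base, spawn_key=(fold, stream)).generate_state(1)[0] >> 1)


def losocv(segset: SegmentSet, cfg: LosocvConfig) -> EvalReport:
    """Leave-one-subject-out evaluation of the configured pipeline.

    Every fold holds out all segments of one user; augmentation,
    imputation, selection and model fitting see only the remaining
    users.  Metrics are averaged over folds and confusion matrices
    summed.
    """
    users = segset.users()
    if len(users) < 2:
        raise ValueError("LOSOCV needs at least 2 users")
    classes = segset.classes(cfg.target)
    report = EvalReport(classes=classes)
    all_true, all_pred = [], []
    for fold, user in enumerate(users):
        test = segset.subset(lambda s: s.user_id == user)
        train = segset.subset(lambda s: s.user_id != user)
        prov = FoldProvenance(held_out_user=user,
                              test_uids=test.uids(), train_uids=train.uids())
        if cfg.target == "activity":
            missing = set(classes) - set(train.labels("activity"))
            if missing and cfg.augment_types is None:
                warnings.warn(f"fold {user}: classes {sorted(missing)} absent "
                              f"from training data", stacklevel=2)
        if cfg.augment_types is not None:
            counts = train.class_counts(cfg.target)
            A = int(np.ceil(cfg.augment_factor * max(counts.values())))
            params = cfg.augment_params or default_params(
                float(np.std(np.concatenate([s.samples for s in train]))))
            plan = AugmentationPlan(A=A, types=cfg.augment_types, params=params,
                                    seed=_fold_seed(cfg.seed, fold, 0))
            prov.augmentation_pool_uids = train.uids()
            train = balance_augment(train, plan, target=cfg.target)
        # classical branch: 117 statistical features
        train_tab = build_feature_table(train, cfg.filter_settings)
        test_tab = build_feature_table(test, cfg.filter_settings)
        selected = None
        if cfg.selection_enabled:
            pruned, plog, zvar = correlation_prune(train_tab,
                                                   cfg.correlation_threshold)
            ranked = importance_rank(pruned, cfg.target,
                                     forest_seed=_fold_seed(cfg.seed, fold, 1),
                                     n_estimators=min(cfg.rf_estimators, 200),
                                     prune_log=plog, zero_variance=zvar)
            protocol = _inner_rf_protocol(cfg, fold)
            sel = saturation_select(ranked, pruned, protocol,
                                    epsilon=cfg.selection_epsilon)
            selected = sel.selected
            prov.selection_uids = train.uids()
        rf = RandomForestModel(classes, n_estimators=cfg.rf_estimators,
                               seed=_fold_seed(cfg.seed, fold, 2))
        rf.fit(train_tab, cfg.target, features=selected)
        prov.model_training_uids = train.uids()
        prob_list, beta_list = [rf.predict_proba(test_tab)], [cfg.betas.rnf]
        if cfg.scnn is not None:
            scnn_cfg = SCNNConfig(**{**cfg.scnn.__dict__,
                                     "seed": _fold_seed(cfg.seed, fold, 3)})
            Xtr = channel_tensor(train, cfg.scnn_input_len, scnn_cfg.channels,
                                 cfg.filter_settings)
            Xte = channel_tensor(test, cfg.scnn_input_len, scnn_cfg.channels,
                                 cfg.filter_settings)
            label_attr = "activity" if cfg.target == "activity" else "user"
            ytr = np.array([classes.index(l) for l in train.labels(label_attr)])
            model = build_scnn(scnn_cfg, cfg.scnn_input_len, len(classes), classes)
            model.fit(Xtr, ytr)
            prob_list.append(model.predict_proba(Xte))
            beta_list.append(cfg.betas.scnn)
        pred_idx, _ = fuse(prob_list, beta_list)
        y_pred = [classes[i] for i in pred_idx]
        y_true = list(test.labels(cfg.target))
        fold_metrics = compute_metrics(y_true, y_pred, classes)
        fold_metrics["confusion"] = fold_metrics["confusion"].tolist()
        fold_metrics["user"] = user
        report.per_fold.append(fold_metrics)
        report.fold_users.append(user)
        report.provenance.append(prov)
        all_true.extend(y_true)
        all_pred.extend(y_pred)
    agg = compute_metrics(all_true, all_pred, classes)
    report.confusion = agg["confusion"]
    report.accuracy = float(np.mean([f["accuracy"] for f in report.per_fold]))
    report.precision = float(np.mean([f["precision"] for f in report.per_fold]))
    report.recall = float(np.mean([f["recall"] for f in report.per_fold]))
    report.f1 = float(np.mean([f["f1"] for f in report.per_fold]))
    cm = report.confusion
    totals = cm.sum(axis=1)
    report.per_class_recall = {
        cls: (100 * cm[i, i] / totals[i] if totals[i] else 0.0)
        for i, cls in enumerate(classes)}
    return report


def _inner_rf_protocol(cfg: LosocvConfig, fold: int):
    """Accuracy of a small RF under inner LOSOCV, for saturation curves."""

    def protocol(table: pd.DataFrame, feats) -> float:
        feats = list(feats)
        label = "activity_id" if cfg.target == "activity" else "user_id"
        users = sorted(table["user_id"].unique())
        if len(users) < 2:
            raise ValueError("saturation protocol needs >= 2 training users")
        correct = total = 0
        for u in users:
            tr = table[table["user_id"] != u]
            te = table[table["user_id"] == u]
            if te.empty or tr[label].nunique() < 2:
                continue
            f = RandomForestClassifier(n_estimators=100, n_jobs=1,
                                       random_state=_fold_seed(cfg.seed, fold, 4))
            f.fit(tr[feats].to_numpy(dtype=float), tr[label].to_numpy())
            pred = f.predict(te[feats].to_numpy(dtype=float))
            correct += int((pred == te[label].to_numpy()).sum())
            total += len(te)
        return correct / total if total else 0.0

    return protocol


def assert_no_leakage(report: EvalReport) -> None:
    """Raise if any held-out segment fed a fitted statistic of its fold."""
    for prov in report.provenance:
        test = prov.test_uids
        for name in ("train_uids", "augmentation_pool_uids",
                     "imputation_uids", "selection_uids",
                     "model_training_uids"):
            pool = getattr(prov, name)
            overlap = {u for u in pool
                       if u in test or any(u.startswith(t + "-aug") for t in test)}
            if overlap:
                raise AssertionError(
                    f"fold {prov.held_out_user}: held-out segments leaked into "
                    f"{name}: {sorted(overlap)[:5]}")
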