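"""Feature selection: correlation pruning, impurity ranking, saturation cut.

The procedure is the standard three stages used with random-forest
pipelines: (1) drop one feature of every pair whose Pearson |r| exceeds a
threshold, (2) rank survivors by mean decrease in impurity (MDI) from a
seeded random forest, (3) walk the accuracy-vs-top-k curve and keep the
smallest k at which accuracy has saturated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import feature_columns


@dataclass
class PruneLogEntry:
    kept: str
    dropped: str
    abs_r: float


@dataclass
class RankedFeatures:
    """MDI-ordered feature names with unit-sum importance scores."""

    names: list[str]
    scores: np.ndarray
    prune_log: list[PruneLogEntry] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if (s < 0).any():
            raise ValueError("importance scores must be non-negative")
        if s.sum() > 0 and abs(s.sum() - 1.0) > 1e-6:
            raise ValueError("importance scores must sum to 1")
        self.scores = s


@dataclass
class SelectionResult:
    selected: list[str]
    k: int
    curve: list[tuple[int, float]]  # (k, accuracy)


def correlation_prune(table: pd.DataFrame, threshold: float = 0.9,
                      ) -> tuple[pd.DataFrame, list[PruneLogEntry], list[str]]:
    """Drop the later column of every surviving pair with |r| > threshold.

    Scans upper-triangle pairs in canonical column order; a pair is acted
    on only if both members are still present, so the scan is greedy and
    deterministic.  Zero-variance columns (undefined correlation) are
    retained and reported separately.  Returns (pruned table, drop log,
    zero-variance column names).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    feats = feature_columns(table)
    if len(table) < 2:
        raise ValueError("correlation pruning needs at least 2 rows")
    X = table[feats].to_numpy(dtype=float)
    sd = X.std(axis=0)
    zero_var = [f for f, s in zip(feats, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    alive = {f: True for f in feats}
    log: list[PruneLogEntry] = []
    for i in range(len(feats)):
        if not alive[feats[i]] or sd[i] == 0:
            continue
        for j in range(i + 1, len(feats)):
            if not alive[feats[j]] or sd[j] == 0:
                continue
            r = abs(corr[i, j])
            if r > threshold:
                alive[feats[j]] = False
                log.append(PruneLogEntry(kept=feats[i], dropped=feats[j], abs_r=float(r)))
    keep = [f for f in feats if alive[f]]
    label_cols = [c for c in table.columns if c not in feats]
    return table[keep + label_cols].copy(), log, zero_var


def importance_rank(table: pd.DataFrame, target: str = "activity",
                    forest_seed: int = 0, n_estimators: int = 500,
                    prune_log: list[PruneLogEntry] | None = None,
                    zero_variance: list[str] | None = None) -> RankedFeatures:
    """Rank features by random-forest mean decrease in impurity."""
    feats = feature_columns(table)
    label = "activity_id" if target == "activity" else "user_id"
    if "segment_uid" in table.columns:
        # fit on a canonical row order so the ranking does not depend on
        # how the caller happened to order the table
        table = table.sort_values("segment_uid", kind="stable")
    y = table[label].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"need at least 2 classes in {label!r} to rank features")
    forest = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=forest_seed, n_jobs=1)
    forest.fit(table[feats].to_numpy(dtype=float), y)
    order = np.argsort(-forest.feature_importances_, kind="stable")
    return RankedFeatures(
        names=[feats[i] for i in order],
        scores=forest.feature_importances_[order],
        prune_log=prune_log or [],
        zero_variance=zero_variance or [])


def default_k_grid(n_features: int) -> list[int]:
    """Every k up to 60, then strides of 5, always ending at n_features."""
    grid = list(range(1, min(60, n_features) + 1))
    grid += list(range(65, n_features + 1, 5))
    if grid[-1] != n_features:
        grid.append(n_features)
    return grid


def saturation_select(ranked: RankedFeatures, table: pd.DataFrame,
                      eval_protocol: Callable[[pd.DataFrame, Sequence[str]], float],
                      epsilon: float = 0.005,
                      k_grid: Sequence[int] | None = None) -> SelectionResult:
    """Smallest top-k whose accuracy clears the saturation plateau.

    Evaluates ``eval_protocol(table, top_k_names)`` over the k grid and
    returns the smallest k with accuracy strictly above
    ``max(curve) - epsilon``; when no k clears it (e.g. epsilon 0 on a
    strictly increasing curve) the full set is returned.
    """
    if not ranked.names:
        raise ValueError("ranked feature list is empty")
    grid = list(k_grid) if k_grid is not None else default_k_grid(len(ranked.names))
    curve = [(k, float(eval_protocol(table, ranked.names[:k]))) for k in grid]
    best = max(acc for _, acc in curve)
    for k, acc in curve:
        if acc > best - epsilon:
            return SelectionResult(ranked.names[:k], k, curve)
    k = grid[-1]
    return SelectionResult(ranked.names[:k], k, curve)
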