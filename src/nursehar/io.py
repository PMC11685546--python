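"""Reading, cleaning and merging the two sensor/label CSV dialects.

Dialect ``ds1`` is segment-keyed: sensor rows carry
``(segment_id, elapsed_time, ax, ay, az)`` and labels
``(user, segment_id, activity)``.  Dialect ``ds2`` is timestamp-keyed:
sensor rows carry ``(timestamp, ax, ay, az)`` and labels
``(user, activity, start_time, finish_time)``; a sample belongs to a label
when ``start_time <= t <= finish_time`` (closed interval).

All timestamps are normalized to float seconds (ISO-8601 strings are
converted to seconds since the Unix epoch).  Sample tables are plain
pandas DataFrames with those canonical columns.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    AXES,
    DS1_LABEL_COLUMNS,
    DS1_SENSOR_COLUMNS,
    DS2_LABEL_COLUMNS,
    DS2_SENSOR_COLUMNS,
    AmbiguousLabelError,
    FormatError,
    RowParseError,
    Segment,
    SegmentSet,
    UnrecoverableColumnError,
)

log = logging.getLogger(__name__)


@dataclass
class MergeSummary:
    """Bookkeeping emitted by :func:`merge_labels` / :func:`window_segments`."""

    n_samples: int = 0
    n_matched: int = 0
    n_dropped_unlabeled: int = 0
    n_short_kept: int = 0
    n_short_dropped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _canonical_seconds(values: pd.Series) -> pd.Series:
    """Convert a timestamp column to float seconds.

    Numeric values pass through; anything else is parsed as ISO-8601.
    """
    numeric = pd.to_numeric(values, errors="coerce")
    out = numeric.astype(float)
    bad = numeric.isna() & values.notna()
    if bad.any():
        parsed = pd.to_datetime(values[bad], errors="coerce", utc=True, format="ISO8601")
        still_bad = parsed.isna()
        if still_bad.any():
            row = int(still_bad[still_bad].index[0])
            raise RowParseError(f"unparseable timestamp {values.loc[row]!r}", row)
        out.loc[bad] = parsed.astype("int64") / 1e9
    return out


def read_sensor_csv(path: str | os.PathLike, dialect: str) -> pd.DataFrame:
    """Read a sensor CSV into a canonical sample table.

    Returns a DataFrame with columns :data:`DS1_SENSOR_COLUMNS` or
    :data:`DS2_SENSOR_COLUMNS` depending on ``dialect``; timestamps in
    float seconds, acceleration columns numeric.
    """
    required = _sensor_columns(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} for dialect {dialect!r}")
    df = df[list(required)].copy()
    if dialect == "ds2":
        df["timestamp"] = _canonical_seconds(df["timestamp"])
    else:
        df["segment_id"] = pd.to_numeric(df["segment_id"], errors="raise").astype(int)
        df["elapsed_time"] = pd.to_numeric(df["elapsed_time"], errors="raise").astype(float)
    for ax in AXES:
        df[ax] = pd.to_numeric(df[ax], errors="coerce").astype(float)
    return df


def read_label_csv(path: str | os.PathLike, dialect: str) -> pd.DataFrame:
    """Read a label CSV (``ds1``: per-segment; ``ds2``: per-interval)."""
    required = DS1_LABEL_COLUMNS if dialect == "ds1" else DS2_LABEL_COLUMNS
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} for dialect {dialect!r}")
    df = df[list(required)].copy()
    if dialect == "ds1":
        df["segment_id"] = pd.to_numeric(df["segment_id"], errors="raise").astype(int)
    else:
        df["start_time"] = _canonical_seconds(df["start_time"])
        df["finish_time"] = _canonical_seconds(df["finish_time"])
        if (df["start_time"] > df["finish_time"]).any():
            raise FormatError("label interval with start_time > finish_time")
    df["user"] = df["user"].astype(str)
    df["activity"] = df["activity"].astype(str)
    return df


def _sensor_columns(dialect: str):
    if dialect == "ds1":
        return DS1_SENSOR_COLUMNS
    if dialect == "ds2":
        return DS2_SENSOR_COLUMNS
    raise ValueError(f"unknown dialect {dialect!r}")


def normalize_and_sort(samples: pd.DataFrame, dialect: str) -> pd.DataFrame:
    """Stable sort by timestamp (ds2) or (segment_id, elapsed_time) (ds1)."""
    if dialect == "ds2":
        keys = ["timestamp"]
    else:
        keys = ["segment_id", "elapsed_time"]
    return samples.sort_values(keys, kind="stable", ignore_index=True)


def impute_missing(samples: pd.DataFrame,
                   means: dict[str, float] | None = None) -> pd.DataFrame:
    """Replace missing acceleration values by their column means.

    If ``means`` is given (e.g. training-set means), those are used instead
    of the table's own means — this is how leakage across a train/test
    split is avoided.
    """
    out = samples.copy()
    for ax in AXES:
        col = out[ax]
        if means is not None:
            m = means[ax]
        else:
            if col.notna().sum() == 0:
                raise UnrecoverableColumnError(f"column {ax!r} is entirely missing")
            m = float(col.mean())
        if np.isnan(m):
            raise UnrecoverableColumnError(f"no mean available for column {ax!r}")
        out[ax] = col.fillna(m)
    return out


def column_means(samples: pd.DataFrame) -> dict[str, float]:
    """Per-axis means over non-missing values (imputation statistics)."""
    return {ax: float(samples[ax].mean()) for ax in AXES}


def merge_labels(samples: pd.DataFrame, labels: pd.DataFrame, dialect: str,
                 sampling_rate: float, overlap_policy: str = "error",
                 ) -> tuple[SegmentSet, MergeSummary]:
    """Join labeled windows out of a sorted, imputed sample table.

    ds1: one segment per distinct ``segment_id`` that has a label row.
    ds2: one segment per label interval, containing exactly the samples
    with ``start_time <= t <= finish_time``.  Samples covered by no label
    are dropped and counted in the returned :class:`MergeSummary`.

    ``overlap_policy`` controls overlapping ds2 intervals that claim the
    same sample: ``"error"`` (default) or ``"first-wins"``.
    """
    summary = MergeSummary(n_samples=len(samples))
    segset = SegmentSet()
    if dialect == "ds1":
        by_sid = dict(tuple(samples.groupby("segment_id", sort=True)))
        for _, row in labels.iterrows():
            sid = int(row["segment_id"])
            grp = by_sid.get(sid)
            if grp is None or len(grp) < 2:
                continue
            arr = grp[list(AXES)].to_numpy(dtype=float)
            segset.add(Segment(arr, sampling_rate, str(row["activity"]),
                               str(row["user"]), uid=f"ds1-{sid}"))
            summary.n_matched += len(grp)
    elif dialect == "ds2":
        t = samples["timestamp"].to_numpy()
        claimed = np.full(len(samples), -1, dtype=int)
        lab = labels.reset_index(drop=True)
        for i, row in lab.iterrows():
            mask = (t >= row["start_time"]) & (t <= row["finish_time"])
            clash = mask & (claimed >= 0)
            if clash.any():
                if overlap_policy == "error":
                    offenders = sorted(set(claimed[clash]) | {i})
                    detail = ", ".join(
                        f"[{lab.loc[j, 'start_time']}, {lab.loc[j, 'finish_time']}]"
                        for j in offenders)
                    raise AmbiguousLabelError(
                        f"overlapping label intervals claim the same samples: {detail}")
                mask &= claimed < 0  # first-wins
            claimed[mask] = i
            if mask.sum() < 2:
                continue
            arr = samples.loc[mask, list(AXES)].to_numpy(dtype=float)
            segset.add(Segment(arr, sampling_rate, str(row["activity"]),
                               str(row["user"]), uid=f"ds2-{i}"))
            summary.n_matched += int(mask.sum())
        summary.n_dropped_unlabeled = int((claimed < 0).sum())
        if summary.n_dropped_unlabeled:
            log.info("merge_labels: dropped %d unlabeled samples",
                     summary.n_dropped_unlabeled)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "ds1":
        labeled_sids = set(labels["segment_id"].astype(int))
        unlabeled = ~samples["segment_id"].isin(labeled_sids)
        summary.n_dropped_unlabeled = int(unlabeled.sum())
    return segset, summary


def window_segments(segset: SegmentSet, window: int, stride: int,
                    drop_short: bool = False,
                    ) -> tuple[SegmentSet, MergeSummary]:
    """Slice segments into fixed-length sliding windows.

    Segments longer than ``window`` are replaced by windows of exactly
    ``window`` samples (labels inherited); shorter segments are kept whole
    (flagged in the summary) or dropped when ``drop_short`` is true.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = SegmentSet()
    summary = MergeSummary()
    for seg in segset:
        n = len(seg)
        if n < window:
            if drop_short:
                summary.n_short_dropped += 1
            else:
                summary.n_short_kept += 1
                out.add(seg)
            continue
        for w, start in enumerate(range(0, n - window + 1, stride)):
            out.add(seg.with_samples(seg.samples[start:start + window],
                                     uid=f"{seg.uid}w{w}"))
    return out, summary


SEGMENT_STORE_COLUMNS = ("segment_uid", "sample_idx", "ax", "ay", "az",
                         "activity_id", "user_id", "source_id")


def write_segments(segset: SegmentSet, csv_path: str | os.PathLike,
                   manifest_path: str | os.PathLike | None = None,
                   dialect: str | None = None, extra: dict | None = None) -> None:
    """Persist a segment store as long-format CSV plus a JSON manifest."""
    frames = []
    for seg in segset:
        n = len(seg)
        frames.append(pd.DataFrame({
            "segment_uid": [seg.uid] * n,
            "sample_idx": np.arange(n),
            "ax": seg.samples[:, 0],
            "ay": seg.samples[:, 1],
            "az": seg.samples[:, 2],
            "activity_id": [seg.activity_id] * n,
            "user_id": [seg.user_id] * n,
            "source_id": [seg.source_id] * n,
        }))
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=list(SEGMENT_STORE_COLUMNS))
    table.to_csv(csv_path, index=False, float_format="%.17g")
    if manifest_path is not None:
        rates = {s.sampling_rate for s in segset}
        manifest = {
            "n_segments": len(segset),
            "sampling_rate": rates.pop() if len(rates) == 1 else sorted(rates),
            "dialect": dialect,
        }
        if extra:
            manifest.update(extra)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)


def read_segments(csv_path: str | os.PathLike, sampling_rate: float) -> SegmentSet:
    """Load a segment store written by :func:`write_segments`."""
    table = pd.read_csv(csv_path, float_precision="round_trip")
    segset = SegmentSet()
    if table.empty:
        return segset
    for uid, grp in table.groupby("segment_uid", sort=False):
        grp = grp.sort_values("sample_idx", kind="stable")
        segset.add(Segment(
            grp[list(AXES)].to_numpy(dtype=float), sampling_rate,
            str(grp["activity_id"].iloc[0]), str(grp["user_id"].iloc[0]),
            source_id=str(grp["source_id"].iloc[0]), uid=str(uid)))
    return segset
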