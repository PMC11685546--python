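"""Core data model for accelerometer activity recognition.

A :class:`Segment` is the unit of classification: one contiguous,
singly-labeled window of tri-axial acceleration samples.  A
:class:`SegmentSet` is an ordered collection of segments with grouping
helpers by activity and user.

Raw sample tables and label tables are carried as :class:`pandas.DataFrame`
objects with documented column contracts (see :mod:`nursehar.io`); the
dataclasses here hold the parsed, merged results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np

AXES = ("ax", "ay", "az")

#: Canonical column sets for the two CSV dialects.
DS1_SENSOR_COLUMNS = ("segment_id", "elapsed_time", "ax", "ay", "az")
DS2_SENSOR_COLUMNS = ("timestamp", "ax", "ay", "az")
DS1_LABEL_COLUMNS = ("user", "segment_id", "activity")
DS2_LABEL_COLUMNS = ("user", "activity", "start_time", "finish_time")


class FormatError(ValueError):
    """A CSV file does not match the declared dialect."""


class RowParseError(ValueError):
    """A specific row could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"{message} (row {row})")
        self.row = row


class UnrecoverableColumnError(ValueError):
    """An acceleration column has no non-missing value to impute from."""


class AmbiguousLabelError(ValueError):
    """Overlapping label intervals claim the same sample."""


@dataclass(frozen=True)
class Segment:
    """One labeled window of tri-axial acceleration.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)`` holding (ax, ay, az) rows in time order.
    sampling_rate
        Sampling frequency in Hz.
    activity_id, user_id
        Categorical labels.
    source_id
        Provenance: ``"original"`` or the augmentation operator name(s).
    uid
        Unique identifier within a dataset; used for provenance audits.
    """

    samples: np.ndarray
    sampling_rate: float
    activity_id: str
    user_id: str
    source_id: str = "original"
    uid: str = ""

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("a segment needs at least 2 samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.isnan(arr).any():
            raise ValueError("segment contains missing values; impute first")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.shape[0]

    def with_samples(self, samples: np.ndarray, source_id: str | None = None,
                     uid: str | None = None) -> "Segment":
        """Copy of this segment with new sample values (labels preserved)."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            source_id=self.source_id if source_id is None else source_id,
            uid=self.uid if uid is None else uid,
        )


class SegmentSet:
    """Ordered collection of :class:`Segment` with label-group indexing."""

    def __init__(self, segments: Iterable[Segment] = ()):
        self.segments: list[Segment] = list(segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    def add(self, seg: Segment) -> None:
        self.segments.append(seg)

    def labels(self, target: str = "activity") -> np.ndarray:
        attr = "activity_id" if target == "activity" else "user_id"
        return np.array([getattr(s, attr) for s in self.segments])

    def classes(self, target: str = "activity") -> list[str]:
        return sorted(set(self.labels(target)))

    def users(self) -> list[str]:
        return sorted({s.user_id for s in self.segments})

    def by_class(self, target: str = "activity") -> dict[str, list[Segment]]:
        groups: dict[str, list[Segment]] = {}
        attr = "activity_id" if target == "activity" else "user_id"
        for s in self.segments:
            groups.setdefault(getattr(s, attr), []).append(s)
        return groups

    def class_counts(self, target: str = "activity") -> dict[str, int]:
        return {k: len(v) for k, v in sorted(self.by_class(target).items())}

    def subset(self, keep) -> "SegmentSet":
        """New set with the segments for which ``keep(segment)`` is true."""
        return SegmentSet(s for s in self.segments if keep(s))

    def uids(self) -> set[str]:
        return {s.uid for s in self.segments}
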