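"""Two-step feature extraction for tri-axial acceleration segments.

Step one builds the 13-column intermediate feature set (IFS) per sample:
the three filtered acceleration axes, the vector magnitude, per-axis
displacement and velocity (second- and first-order cumulative trapezoid
integrals), and per-axis orientation angles
``theta_a = arctan(a / sqrt(b^2 + c^2))``.

Step two reduces each IFS column to 9 statistics — sd, average, max, min,
variance, median absolute deviation, MSUM, energy and interquartile
range — giving the 13 x 9 = 117-value final feature set (FFS).

MSUM is the mean absolute value-gap between each relative extremum and
its *second* successive opposite extremum: it summarizes the longer-range
oscillation structure that max/min/mean alone miss.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .datamodel import Segment, SegmentSet

IFS_COLUMNS = ("ax", "ay", "az", "magnitude",
               "disp_x", "disp_y", "disp_z",
               "vel_x", "vel_y", "vel_z",
               "angle_x", "angle_y", "angle_z")

STAT_NAMES = ("sd", "avg", "max", "min", "var", "mad", "msum", "energy", "iqr")

#: Canonical FFS feature names, column-major over IFS columns then stats.
FEATURE_NAMES = tuple(f"{col}_{stat}" for col in IFS_COLUMNS for stat in STAT_NAMES)

LABEL_COLUMNS = ("activity_id", "user_id", "segment_uid")


class NyquistWarning(UserWarning):
    """The low-pass cutoff is at or above Nyquist; the filter is skipped."""


@dataclass(frozen=True)
class FilterSettings:
    """Pre-feature denoising: running median then zero-phase Butterworth."""

    median_window: int = 5
    cutoff_hz: float = 20.0
    butter_order: int = 3


@dataclass(frozen=True)
class IFSMatrix:
    """Per-sample 13-column intermediate feature matrix for one segment."""

    data: np.ndarray  # (n, 13), column order IFS_COLUMNS
    sampling_rate: float

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[1] != len(IFS_COLUMNS):
            raise ValueError(f"IFS must have {len(IFS_COLUMNS)} columns")

    def column(self, name: str) -> np.ndarray:
        return self.data[:, IFS_COLUMNS.index(name)]


def median_filter(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered running median; the window shrinks at the edges."""
    if window % 2 == 0 or window < 1:
        raise ValueError("median filter window must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    if window == 1:
        return x.copy()
    h = window // 2
    n = len(x)
    out = np.empty(n)
    if n >= window:
        from numpy.lib.stride_tricks import sliding_window_view
        out[h:n - h] = np.median(sliding_window_view(x, window), axis=1)
        edge = h
    else:
        edge = n
    for i in range(min(edge, n)):
        out[i] = np.median(x[max(0, i - h):min(n, i + h + 1)])
    for i in range(max(n - edge, 0), n):
        out[i] = np.median(x[max(0, i - h):min(n, i + h + 1)])
    return out


def butterworth_lowpass(x: np.ndarray, fs: float, cutoff: float = 20.0,
                        order: int = 3) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth, DC gain 1.

    When ``cutoff >= fs/2`` the filter has no valid passband edge; the
    input is returned unchanged with a :class:`NyquistWarning` (this is
    the 4 Hz-data case, where a 20 Hz cutoff is void).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("butterworth_lowpass: input contains non-finite values")
    if cutoff >= fs / 2:
        warnings.warn(
            f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz; filter skipped",
            NyquistWarning, stacklevel=2)
        return x.copy()
    b, a = butter(order, cutoff, btype="low", fs=fs)
    # filtfilt needs padlen < len(x); shrink for short segments
    padlen = min(3 * max(len(a), len(b)), len(x) - 1)
    return filtfilt(b, a, x, padlen=padlen)


def filter_segment(seg: Segment, settings: FilterSettings = FilterSettings()) -> Segment:
    """Apply median + Butterworth filtering to each acceleration axis."""
    with warnings.catch_warnings():
        warnings.simplefilter("once", NyquistWarning)
        cols = [butterworth_lowpass(
                    median_filter(seg.samples[:, a], settings.median_window),
                    seg.sampling_rate, settings.cutoff_hz, settings.butter_order)
                for a in range(3)]
    return seg.with_samples(np.column_stack(cols))


def compute_magnitude(samples: np.ndarray) -> np.ndarray:
    """Per-sample L2 norm of the acceleration vector (orientation-free)."""
    return np.linalg.norm(np.asarray(samples, dtype=float), axis=1)


def compute_angles(samples: np.ndarray) -> np.ndarray:
    """Per-axis orientation angles, shape (n, 3).

    ``theta_a = arctan(a / sqrt(b^2 + c^2))`` with the division-by-zero
    limit ±pi/2 and the all-zero sample mapped to 0 (arctan2 convention).
    """
    s = np.asarray(samples, dtype=float)
    out = np.empty_like(s)
    for a in range(3):
        others = np.sqrt(np.sum(np.delete(s, a, axis=1) ** 2, axis=1))
        out[:, a] = np.arctan2(s[:, a], others)
    return out


def integrate(x: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """Cumulative trapezoidal integral with initial value 0.

    ``order=1`` gives velocity from acceleration; ``order=2`` applies the
    operator twice (displacement).  Output length equals input length.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    out = np.asarray(x, dtype=float)
    for _ in range(order):
        out = cumulative_trapezoid(out, dx=dt, initial=0.0)
    return out


def compute_ifs(seg: Segment) -> IFSMatrix:
    """Assemble the 13-column intermediate feature matrix for a segment."""
    acc = seg.samples
    dt = 1.0 / seg.sampling_rate
    vel = np.column_stack([integrate(acc[:, a], dt, order=1) for a in range(3)])
    disp = np.column_stack([integrate(acc[:, a], dt, order=2) for a in range(3)])
    mag = compute_magnitude(acc)
    ang = compute_angles(acc)
    data = np.column_stack([acc, mag[:, None], disp, vel, ang])
    return IFSMatrix(data, seg.sampling_rate)


def _relative_extrema(x: np.ndarray) -> list[tuple[int, float, int]]:
    """Strict interior extrema as (index, value, kind) with kind +1/-1.

    An extremum is a strict sign change of the first difference; a flat
    plateau contributes only its first index.
    """
    x = np.asarray(x, dtype=float)
    extrema: list[tuple[int, float, int]] = []
    last_sign = 0
    run_start = 0  # first index of the current flat run
    for i in range(1, len(x)):
        d = x[i] - x[i - 1]
        if d == 0:
            continue
        sign = 1 if d > 0 else -1
        if last_sign == 1 and sign == -1:
            extrema.append((run_start, x[run_start], +1))
        elif last_sign == -1 and sign == 1:
            extrema.append((run_start, x[run_start], -1))
        last_sign = sign
        run_start = i
    return extrema


def msum(x: np.ndarray) -> float:
    """Mean absolute gap to the second successive opposite extremum.

    Relative maxima pair with their second successive relative minimum
    and vice versa; extrema lacking a second successor are skipped.  The
    sum of all absolute gaps is divided by the number of contributing
    pairs; a series with no such pair returns 0.
    """
    ext = _relative_extrema(x)
    # extrema alternate in kind, so the second successive opposite
    # extremum of ext[i] is ext[i + 3]
    gaps = [abs(ext[i][1] - ext[i + 3][1]) for i in range(len(ext) - 3)]
    # fsum: correctly rounded, so the value is independent of pairing order
    return math.fsum(gaps) / len(gaps) if gaps else 0.0


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def compute_ffs(ifs: IFSMatrix) -> pd.Series:
    """Reduce each IFS column to the 9 statistics -> 117 named features.

    Energy is the mean of squared values (length-invariant); sd/var use
    the population convention so ``var == sd**2`` exactly.
    """
    values = {}
    for ci, col in enumerate(IFS_COLUMNS):
        x = ifs.data[:, ci]
        sd = float(np.std(x))
        values[f"{col}_sd"] = sd
        values[f"{col}_avg"] = float(np.mean(x))
        values[f"{col}_max"] = float(np.max(x))
        values[f"{col}_min"] = float(np.min(x))
        values[f"{col}_var"] = sd * sd
        values[f"{col}_mad"] = _mad(x)
        values[f"{col}_msum"] = msum(x)
        values[f"{col}_energy"] = float(np.mean(x ** 2))
        values[f"{col}_iqr"] = _iqr(x)
    return pd.Series([values[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES))


def build_feature_table(segset: SegmentSet,
                        settings: FilterSettings = FilterSettings(),
                        prefiltered: bool = False) -> pd.DataFrame:
    """Filter -> IFS -> FFS for every segment; one row per segment.

    Returns a DataFrame with the 117 canonical feature columns followed
    by ``activity_id``, ``user_id`` and ``segment_uid``.
    """
    rows, labels = [], []
    for seg in segset:
        try:
            filtered = seg if prefiltered else filter_segment(seg, settings)
            rows.append(compute_ffs(compute_ifs(filtered)))
        except Exception as exc:  # attach provenance for debugging
            raise RuntimeError(f"feature extraction failed for segment "
                               f"{seg.uid!r}") from exc
        labels.append((seg.activity_id, seg.user_id, seg.uid))
    table = pd.DataFrame(rows).reset_index(drop=True)
    lab = pd.DataFrame(labels, columns=list(LABEL_COLUMNS))
    return pd.concat([table, lab], axis=1)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The non-label columns of a feature table, in table order."""
    return [c for c in table.columns if c not in LABEL_COLUMNS]
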