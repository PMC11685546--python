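"""Seeded synthetic tri-axial accelerometer datasets.

Each (activity, user) pair gets a motion motif: a two-harmonic sinusoid
mixture whose frequencies and per-axis amplitudes are determined by the
activity, superposed on a unit gravity offset, then rotated by the
user's wearing tilt (an axis-angle rotation reused as a forward model of
sensor placement).  Per-segment phase jitter and additive Gaussian noise
supply intra-class variability; the class-count vector controls
imbalance.  Because the user effect is a pure rotation, the magnitude
channel is identical across users at zero noise while the angle channels
carry the user signal — mirroring how orientation-free and orientation
features behave on real wearable data.

Generation is deterministic under a fixed seed and independent of
generation order (one RNG substream per segment, keyed by counter).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import rotation_matrix
from .datamodel import AXES, Segment, SegmentSet


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a balanced 4-activity x 4-user set sampled at 60 Hz
    with 1-2 s segments and mild sensor noise (0.05 g).
    """

    n_users: int = 4
    n_activities: int = 4
    sampling_rate: float = 60.0
    segment_length_range: tuple[int, int] = (60, 120)
    segments_per_class: tuple[int, ...] | None = None  # None -> 12 per class
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_users < 1 or self.n_activities < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.segment_length_range
        if not 2 <= lo <= hi:
            raise ValueError("segment_length_range must satisfy 2 <= min <= max")
        if self.segments_per_class is not None and \
                len(self.segments_per_class) != self.n_activities:
            raise ValueError("segments_per_class length must equal n_activities")

    @property
    def class_counts(self) -> tuple[int, ...]:
        if self.segments_per_class is None:
            return (12,) * self.n_activities
        return tuple(self.segments_per_class)


@dataclass(frozen=True)
class MotifParams:
    """Motion motif for one (activity, user) pair.

    The harmonic structure (frequency, amplitudes, harmonic ratio) is a
    function of the activity only; the tilt is a function of the user
    only, so rotating-out the tilt recovers the activity motif.
    """

    base_freq_hz: float
    amplitudes: tuple[float, float, float]
    harmonic_amplitudes: tuple[float, float, float]
    tilt_axis: tuple[float, float, float]
    tilt_angle: float
    phase_jitter_sd: float = 0.5

    def validate(self, sampling_rate: float) -> None:
        if 2 * self.base_freq_hz >= sampling_rate / 2:
            raise ValueError(
                f"motif harmonic {2 * self.base_freq_hz} Hz reaches Nyquist "
                f"({sampling_rate / 2} Hz)")


def default_motifs(config: GeneratorConfig) -> dict[tuple[int, int], MotifParams]:
    """Deterministic motif table keyed by (activity index, user index)."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0,)))
    # activity-level structure: spread base frequencies, distinct amplitudes
    freqs = [0.8 + 0.7 * a for a in range(config.n_activities)]
    amps = [tuple(rng.uniform(0.3, 0.9, 3)) for _ in range(config.n_activities)]
    hamps = [tuple(rng.uniform(0.1, 0.4, 3)) for _ in range(config.n_activities)]
    # user-level structure: distinct wearing tilts
    tilts = []
    for _ in range(config.n_users):
        axis = rng.uniform(-1.0, 1.0, 3)
        axis /= np.linalg.norm(axis)
        tilts.append((tuple(axis), float(rng.uniform(0.15, 0.6))))
    motifs = {}
    for a in range(config.n_activities):
        for u in range(config.n_users):
            m = MotifParams(freqs[a], amps[a], hamps[a], tilts[u][0], tilts[u][1])
            m.validate(config.sampling_rate)
            motifs[(a, u)] = m
    return motifs


def _motif_signal(motif: MotifParams, length: int, fs: float,
                  rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    t = np.arange(length) / fs
    phases = rng.normal(0.0, motif.phase_jitter_sd, 3)
    base = np.column_stack([
        motif.amplitudes[a] * np.sin(2 * np.pi * motif.base_freq_hz * t + phases[a])
        + motif.harmonic_amplitudes[a]
        * np.sin(2 * np.pi * 2 * motif.base_freq_hz * t + 2 * phases[a])
        for a in range(3)])
    base[:, 2] += 1.0  # gravity-like offset along device z before tilt
    Q = rotation_matrix(motif.tilt_axis, motif.tilt_angle)
    tilted = base @ Q
    if noise_sd > 0:
        tilted = tilted + rng.normal(0.0, noise_sd, tilted.shape)
    return tilted


def generate_dataset(config: GeneratorConfig,
                     motifs: dict[tuple[int, int], MotifParams] | None = None,
                     ) -> SegmentSet:
    """Generate a labeled SegmentSet under the configured conditions.

    Class counts equal ``config.class_counts`` exactly; segments of a
    class are assigned round-robin over users.
    """
    if motifs is None:
        motifs = default_motifs(config)
    for m in motifs.values():
        m.validate(config.sampling_rate)
    segset = SegmentSet()
    counter = 0
    lo, hi = config.segment_length_range
    for a, count in enumerate(config.class_counts):
        for j in range(count):
            u = j % config.n_users
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=config.seed, spawn_key=(1, counter)))
            length = int(rng.integers(lo, hi + 1))
            samples = _motif_signal(motifs[(a, u)], length,
                                    config.sampling_rate, rng, config.noise_sd)
            segset.add(Segment(samples, config.sampling_rate,
                               activity_id=f"A{a + 1}", user_id=f"U{u + 1}",
                               uid=f"syn-{counter}"))
            counter += 1
    return segset


def inject_missing(samples: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank each acceleration cell independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = samples.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for ax in AXES:
        mask = rng.random(len(out)) < rate
        out.loc[mask, ax] = np.nan
    return out


def emit_challenge_csv(segset: SegmentSet, dialect: str,
                       out_dir: str | os.PathLike,
                       gap_seconds: float = 5.0) -> tuple[str, str]:
    """Write sensor + label CSVs in one of the two challenge dialects.

    ds1 keys samples by segment id; ds2 lays segments out on a continuous
    timeline separated by ``gap_seconds`` so label intervals are disjoint.
    Returns ``(sensor_path, label_path)``.
    """
    os.makedirs(out_dir, exist_ok=True)
    sensor_path = os.path.join(out_dir, f"{dialect}_sensor.csv")
    label_path = os.path.join(out_dir, f"{dialect}_labels.csv")
    sensor_rows, label_rows = [], []
    t0 = 0.0
    for sid, seg in enumerate(segset):
        n = len(seg)
        fs = seg.sampling_rate
        if dialect == "ds1":
            for i in range(n):
                sensor_rows.append((sid, i / fs, *seg.samples[i]))
            label_rows.append((seg.user_id, sid, seg.activity_id))
        elif dialect == "ds2":
            times = t0 + np.arange(n) / fs
            for i in range(n):
                sensor_rows.append((times[i], *seg.samples[i]))
            label_rows.append((seg.user_id, seg.activity_id,
                               times[0], times[-1]))
            t0 = times[-1] + gap_seconds
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "ds1":
        pd.DataFrame(sensor_rows, columns=["segment_id", "elapsed_time",
                                           "ax", "ay", "az"]).to_csv(
            sensor_path, index=False, float_format="%.17g")
        pd.DataFrame(label_rows, columns=["user", "segment_id", "activity"]
                     ).to_csv(label_path, index=False)
    else:
        pd.DataFrame(sensor_rows, columns=["timestamp", "ax", "ay", "az"]
                     ).to_csv(sensor_path, index=False, float_format="%.17g")
        pd.DataFrame(label_rows, columns=["user", "activity",
                                          "start_time", "finish_time"]
                     ).to_csv(label_path, index=False, float_format="%.17g")
    return sensor_path, label_path
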