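"""Label-preserving time-series augmentation for tri-axial segments.

Five operators — jitter, scaling, magnitude warping (MW), time warping
(TW) and rotation — plus a class-balancing driver that grows every
activity group to the same target count by cycling its original segments
through the configured operator(s).

All operators preserve the segment's labels and length.  Warp curves are
natural cubic splines through ``phi + 2`` Gaussian knots placed on an
equally spaced grid over the segment's index range; one curve is shared
by the three axes so inter-axis geometry is preserved.  Rotation applies
a random axis-angle matrix to each sample row-vector and therefore leaves
the per-sample vector magnitude untouched — magnitude-derived features
are rotation-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .datamodel import Segment, SegmentSet

OPERATOR_NAMES = ("jitter", "scaling", "mw", "tw", "rot")


@dataclass(frozen=True)
class NoiseParams:
    """Gaussian parameters for jitter (additive) and scaling (multiplicative)."""

    mu: float = 0.0
    sigma: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class WarpParams:
    """Random-curve parameters: ``phi + 2`` knots drawn from N(mu, sigma)."""

    phi: int = 4
    mu: float = 1.0
    sigma: float = 0.2

    def __post_init__(self):
        if self.phi < 1:
            raise ValueError("phi must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class RotationDraw:
    """A concrete rotation: unit axis and angle in radians."""

    axis: tuple[float, float, float]
    theta: float

    def __post_init__(self):
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        if not -np.pi <= self.theta <= np.pi:
            raise ValueError("theta must lie in [-pi, pi]")


def default_params(signal_sd: float = 1.0) -> dict:
    """Default operator parameters, scaled to the signal's amplitude.

    Jitter noise N(0, 0.03*sd of the signal), scaling N(1, 0.1), warp
    knots N(1, 0.2) with curve complexity phi=4.
    """
    return {
        "jitter": NoiseParams(0.0, 0.03 * signal_sd),
        "scaling": NoiseParams(1.0, 0.1),
        "mw": WarpParams(4, 1.0, 0.2),
        "tw": WarpParams(4, 1.0, 0.2),
        "rot": None,
    }


@dataclass(frozen=True)
class AugmentationPlan:
    """Target count ``A`` per class and which operator(s) to apply.

    ``types`` is a sequence of operator names; a tuple entry such as
    ``("mw", "tw")`` means composition applied left to right.
    """

    A: int
    types: tuple = (("tw",),)
    params: dict = field(default_factory=default_params)
    seed: int = 0

    def __post_init__(self):
        norm = tuple((t,) if isinstance(t, str) else tuple(t) for t in self.types)
        if not norm:
            raise ValueError("types must be non-empty")
        for chain in norm:
            for op in chain:
                if op not in OPERATOR_NAMES:
                    raise ValueError(f"unknown augmentation type {op!r}")
        object.__setattr__(self, "types", norm)


def jitter(seg: Segment, p: NoiseParams, rng: np.random.Generator) -> Segment:
    """Add i.i.d. Gaussian noise to every sample of every axis."""
    noise = rng.normal(p.mu, p.sigma, seg.samples.shape)
    return seg.with_samples(seg.samples + noise, source_id="jitter")


def scaling(seg: Segment, p: NoiseParams, rng: np.random.Generator) -> Segment:
    """Multiply every sample by an independent Gaussian draw."""
    factors = rng.normal(p.mu, p.sigma, seg.samples.shape)
    return seg.with_samples(seg.samples * factors, source_id="scaling")


def random_curve(m: int, p: WarpParams, rng: np.random.Generator) -> np.ndarray:
    """Natural cubic spline through ``phi + 2`` Gaussian knots.

    Knot positions are equally spaced over ``[0, m-1]``; the curve is
    evaluated at the integer positions ``0..m-1`` and passes through the
    knot values exactly.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    k = p.phi + 2
    positions = np.linspace(0.0, m - 1.0, k)
    values = rng.normal(p.mu, p.sigma, k)
    spline = CubicSpline(positions, values, bc_type="natural")
    return spline(np.arange(m, dtype=float))


def magnitude_warp(seg: Segment, p: WarpParams, rng: np.random.Generator) -> Segment:
    """Multiply all three axes elementwise by one shared random curve."""
    curve = random_curve(len(seg), p, rng)
    return seg.with_samples(seg.samples * curve[:, None], source_id="mw")


def time_warp(seg: Segment, p: WarpParams, rng: np.random.Generator,
              max_retries: int = 10) -> Segment:
    """Resample the segment along a randomly warped time base.

    A random curve ``r`` of the segment's length is cumulatively averaged
    into a warp ``v = cumsum(r)/m``, rescaled to span ``[0, m-1]``, and
    each axis is linearly interpolated back onto the original integer
    grid against that warped base.  Output length equals input length.
    A non-monotone warp (possible when the curve dips negative) is
    redrawn up to ``max_retries`` times.
    """
    m = len(seg)
    for _ in range(max_retries):
        curve = random_curve(m, p, rng)
        cum = np.cumsum(curve) / m
        span = cum[-1] - cum[0]
        if span <= 0 or np.any(np.diff(cum) <= 0):
            continue
        v = (cum - cum[0]) / span * (m - 1)
        grid = np.arange(m, dtype=float)
        warped = np.column_stack(
            [np.interp(grid, v, seg.samples[:, a]) for a in range(3)])
        return seg.with_samples(warped, source_id="tw")
    raise RuntimeError(
        f"time_warp: no monotone warp curve after {max_retries} draws "
        f"(knots N({p.mu}, {p.sigma}))")


def rotation_matrix(axis, theta: float) -> np.ndarray:
    """Axis-angle rotation matrix for right-multiplication of row vectors.

    With ``c = 1 - cos(theta)`` and unit axis ``(x, y, z)``::

        Q = [[x*x*c + cos,  x*y*c - z*sin,  x*z*c + y*sin],
             [y*x*c + z*sin, y*y*c + cos,   y*z*c - x*sin],
             [z*x*c - y*sin, z*y*c + x*sin, z*z*c + cos ]]

    Q is orthogonal, so per-sample magnitudes are preserved exactly.
    """
    x, y, z = np.asarray(axis, dtype=float)
    c = 1.0 - np.cos(theta)
    s, co = np.sin(theta), np.cos(theta)
    return np.array([
        [x * x * c + co, x * y * c - z * s, x * z * c + y * s],
        [y * x * c + z * s, y * y * c + co, y * z * c - x * s],
        [z * x * c - y * s, z * y * c + x * s, z * z * c + co],
    ])


def draw_rotation(rng: np.random.Generator) -> RotationDraw:
    """Random axis (normalized uniform[-1,1]^3 vector) and uniform angle."""
    while True:
        u = rng.uniform(-1.0, 1.0, 3)
        norm = np.linalg.norm(u)
        if norm > 1e-12:
            break
    theta = rng.uniform(-np.pi, np.pi)
    return RotationDraw(tuple(u / norm), theta)


def rotation(seg: Segment, rng: np.random.Generator,
             draw: RotationDraw | None = None) -> Segment:
    """Rotate every sample row-vector by a random axis-angle matrix."""
    if draw is None:
        draw = draw_rotation(rng)
    Q = rotation_matrix(draw.axis, draw.theta)
    return seg.with_samples(seg.samples @ Q, source_id="rot")


def apply_operator(seg: Segment, op: str, params: dict,
                   rng: np.random.Generator) -> Segment:
    if op == "jitter":
        return jitter(seg, params["jitter"], rng)
    if op == "scaling":
        return scaling(seg, params["scaling"], rng)
    if op == "mw":
        return magnitude_warp(seg, params["mw"], rng)
    if op == "tw":
        return time_warp(seg, params["tw"], rng)
    if op == "rot":
        return rotation(seg, rng)
    raise ValueError(f"unknown augmentation type {op!r}")


def apply_chain(seg: Segment, chain: tuple, params: dict,
                rng: np.random.Generator) -> Segment:
    """Apply a composition of operators left to right (e.g. MW then TW)."""
    out = seg
    for op in chain:
        out = apply_operator(out, op, params, rng)
    return out.with_samples(out.samples, source_id="+".join(chain))


def balance_augment(segset: SegmentSet, plan: AugmentationPlan,
                    target: str = "activity") -> SegmentSet:
    """Grow every class group to exactly ``plan.A`` segments.

    Originals are retained unmodified; each group cycles over its original
    segments, applying the plan's operator chain(s) in rotation, until the
    group holds ``A`` segments.  Deterministic for a fixed plan seed
    regardless of processing order (one RNG substream per new segment).
    """
    groups = segset.by_class(target)
    for cls, members in groups.items():
        if not members:
            raise ValueError(f"class {cls!r} has no segments")
    max_count = max(len(m) for m in groups.values())
    if plan.A < max_count:
        raise ValueError(
            f"plan.A={plan.A} is below the current maximum class count {max_count}")
    out = SegmentSet()
    for ci, cls in enumerate(sorted(groups)):
        members = groups[cls]
        for seg in members:
            out.add(seg)
        need = plan.A - len(members)
        for j in range(need):
            base = members[j % len(members)]
            chain = plan.types[j % len(plan.types)]
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=plan.seed,
                                       spawn_key=(ci, j)))
            aug = apply_chain(base, chain, plan.params, rng)
            out.add(aug.with_samples(aug.samples, uid=f"{base.uid}-aug{j}"))
    return out
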