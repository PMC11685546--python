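import numpy as np
import pytest

from nursehar.datamodel import Segment, SegmentSet
from nursehar.synthetic import GeneratorConfig, generate_dataset
from nursehar.io import window_segments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def segment(rng) -> Segment:
    """One 120-sample segment of noisy oscillation."""
    t = np.arange(120) / 60.0
    samples = np.column_stack([
        0.5 * np.sin(2 * np.pi * 2.0 * t),
        0.4 * np.cos(2 * np.pi * 1.5 * t),
        1.0 + 0.3 * np.sin(2 * np.pi * 3.0 * t),
    ]) + rng.normal(0, 0.02, (120, 3))
    return Segment(samples, 60.0, "A1", "U1", uid="fix-0")


@pytest.fixture(scope="session")
def small_dataset() -> SegmentSet:
    """Balanced 4-activity x 4-user synthetic set, windowed to 60 samples."""
    segset = generate_dataset(GeneratorConfig(seed=99))
    windowed, _ = window_segments(segset, 60, 60)
    return windowed


def make_segments(counts: dict[str, int], length: int = 60, fs: float = 60.0,
                  n_users: int = 2, seed: int = 0) -> SegmentSet:
    """Tiny hand-rolled labeled set for structural tests."""
    rng = np.random.default_rng(seed)
    out = SegmentSet()
    uid = 0
    for cls, n in counts.items():
        for j in range(n):
            samples = rng.normal(0, 1, (length, 3))
            out.add(Segment(samples, fs, cls, f"U{j % n_users + 1}",
                            uid=f"t-{uid}"))
            uid += 1
    return out
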