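"""Augmentation operators: identities, invariants, oracle checks, balancing."""

import numpy as np
import pytest

from nursehar.augment import (AugmentationPlan, NoiseParams, WarpParams,
                              balance_augment, default_params, jitter,
                              magnitude_warp, random_curve, rotation,
                              rotation_matrix, scaling, time_warp,
                              RotationDraw)
from conftest import make_segments
from oracles import natural_cubic_spline

OPERATORS = {
    "jitter": lambda seg, rng: jitter(seg, NoiseParams(0, 0.05), rng),
    "scaling": lambda seg, rng: scaling(seg, NoiseParams(1, 0.1), rng),
    "mw": lambda seg, rng: magnitude_warp(seg, WarpParams(4, 1, 0.2), rng),
    "tw": lambda seg, rng: time_warp(seg, WarpParams(4, 1, 0.2), rng),
    "rot": lambda seg, rng: rotation(seg, rng),
}


class TestJitter:
    def test_degenerate_identity(self, segment, rng):
        out = jitter(segment, NoiseParams(0.0, 0.0), rng)
        assert np.array_equal(out.samples, segment.samples)

    def test_clt_mean_bound(self, rng):
        seg = make_segments({"A": 1}, length=4000)[0]  # 12000 draws
        sigma, mu = 0.05, 0.0
        out = jitter(seg, NoiseParams(mu, sigma), rng)
        diff = (out.samples - seg.samples).ravel()
        assert abs(diff.mean() - mu) <= 3 * sigma / np.sqrt(diff.size)

    def test_reproducible(self, segment):
        a = jitter(segment, NoiseParams(0, 0.1), np.random.default_rng(5))
        b = jitter(segment, NoiseParams(0, 0.1), np.random.default_rng(5))
        assert np.array_equal(a.samples, b.samples)


class TestScaling:
    def test_degenerate_identity(self, segment, rng):
        out = scaling(segment, NoiseParams(1.0, 0.0), rng)
        assert np.allclose(out.samples, segment.samples)

    def test_zeros_stay_zero(self, rng):
        seg = make_segments({"A": 1})[0].with_samples(np.zeros((60, 3)))
        out = scaling(seg, NoiseParams(1.0, 0.5), rng)
        assert np.array_equal(out.samples, np.zeros((60, 3)))

    def test_constant_factor(self, segment, rng):
        out = scaling(segment, NoiseParams(2.0, 0.0), rng)
        assert np.allclose(out.samples, 2 * segment.samples)


class TestRandomCurve:
    def test_sigma_zero_is_constant(self, rng):
        curve = random_curve(100, WarpParams(4, 0.7, 0.0), rng)
        assert np.allclose(curve, 0.7)

    def test_passes_through_knots(self):
        rng = np.random.default_rng(8)
        p = WarpParams(phi=3, mu=1.0, sigma=0.5)
        m = 101
        # regenerate the knot draw with the same stream to know the values
        curve = random_curve(m, p, np.random.default_rng(8))
        values = rng.normal(p.mu, p.sigma, p.phi + 2)
        positions = np.linspace(0, m - 1, p.phi + 2)
        on_grid = positions == positions.astype(int)
        for pos, val in zip(positions[on_grid], values[on_grid]):
            assert abs(curve[int(pos)] - val) < 1e-9

    def test_matches_independent_spline_oracle(self):
        p = WarpParams(phi=4, mu=1.0, sigma=0.3)
        m = 100
        curve = random_curve(m, p, np.random.default_rng(77))
        values = np.random.default_rng(77).normal(p.mu, p.sigma, p.phi + 2)
        positions = np.linspace(0, m - 1, p.phi + 2)
        oracle = natural_cubic_spline(positions, values, np.arange(m))
        assert np.allclose(curve, oracle, atol=1e-9)


class TestMagnitudeWarp:
    def test_degenerate_identity(self, segment, rng):
        out = magnitude_warp(segment, WarpParams(4, 1.0, 0.0), rng)
        assert np.allclose(out.samples, segment.samples)

    def test_ratio_equals_shared_curve(self, segment):
        p = WarpParams(4, 1.0, 0.2)
        out = magnitude_warp(segment, p, np.random.default_rng(3))
        curve = random_curve(len(segment), p, np.random.default_rng(3))
        nz = segment.samples != 0
        ratio = np.where(nz, out.samples / np.where(nz, segment.samples, 1), 0)
        for a in range(3):
            mask = nz[:, a]
            assert np.allclose(ratio[mask, a], curve[mask], atol=1e-9)


class TestTimeWarp:
    def test_constant_curve_is_identity(self, segment, rng):
        out = time_warp(segment, WarpParams(4, 1.0, 0.0), rng)
        assert np.allclose(out.samples, segment.samples, atol=1e-9)

    def test_endpoints_preserved(self, segment):
        out = time_warp(segment, WarpParams(4, 1.0, 0.2),
                        np.random.default_rng(4))
        assert np.allclose(out.samples[0], segment.samples[0], atol=1e-9)
        assert np.allclose(out.samples[-1], segment.samples[-1], atol=1e-9)

    def test_monotone_input_stays_monotone(self):
        ramp = np.linspace(0, 1, 80)
        seg = make_segments({"A": 1}, length=80)[0].with_samples(
            np.column_stack([ramp, ramp, ramp]))
        for s in range(100):
            out = time_warp(seg, WarpParams(4, 1.0, 0.2),
                            np.random.default_rng(s))
            assert np.all(np.diff(out.samples[:, 0]) >= -1e-12)

    def test_length_preserved(self, segment):
        out = time_warp(segment, WarpParams(4, 1.0, 0.2),
                        np.random.default_rng(9))
        assert len(out) == len(segment)


class TestRotation:
    def test_zero_angle_identity(self, segment, rng):
        out = rotation(segment, rng, draw=RotationDraw((0.0, 0.0, 1.0), 0.0))
        assert np.allclose(out.samples, segment.samples, atol=1e-12)

    def test_worked_case_z_axis_quarter_turn(self):
        Q = rotation_matrix((0.0, 0.0, 1.0), np.pi / 2)
        assert np.allclose(Q, [[0, -1, 0], [1, 0, 0], [0, 0, 1]], atol=1e-12)
        assert np.allclose(np.array([1.0, 0.0, 0.0]) @ Q, [0, -1, 0],
                           atol=1e-12)

    def test_magnitude_preserved(self, segment):
        for s in range(20):
            out = rotation(segment, np.random.default_rng(s))
            before = np.linalg.norm(segment.samples, axis=1)
            after = np.linalg.norm(out.samples, axis=1)
            assert np.max(np.abs(after - before)) < 1e-9


class TestOperatorContracts:
    @pytest.mark.parametrize("name", sorted(OPERATORS))
    def test_labels_and_length_preserved(self, segment, name):
        out = OPERATORS[name](segment, np.random.default_rng(1))
        assert len(out) == len(segment)
        assert out.activity_id == segment.activity_id
        assert out.user_id == segment.user_id
        assert out.sampling_rate == segment.sampling_rate

    @pytest.mark.parametrize("name", sorted(OPERATORS))
    def test_pure_function_of_seed(self, segment, name):
        a = OPERATORS[name](segment, np.random.default_rng(2))
        b = OPERATORS[name](segment, np.random.default_rng(2))
        assert np.array_equal(a.samples, b.samples)


class TestBalanceAugment:
    def test_counts_forced_to_target(self):
        segset = make_segments({"A": 5, "B": 2})
        plan = AugmentationPlan(A=5, types=("tw",), seed=1)
        out = balance_augment(segset, plan)
        assert out.class_counts() == {"A": 5, "B": 5}
        assert sum(1 for s in out if s.source_id != "original") == 3

    def test_already_balanced_is_identity(self):
        segset = make_segments({"A": 3, "B": 3})
        out = balance_augment(segset, AugmentationPlan(A=3, types=("jitter",)))
        assert len(out) == len(segset)
        assert all(s.source_id == "original" for s in out)

    def test_degenerate_jitter_duplicates_cycled_originals(self):
        segset = make_segments({"A": 3, "B": 1})
        plan = AugmentationPlan(
            A=3, types=("jitter",),
            params={**default_params(), "jitter": NoiseParams(0.0, 0.0)})
        out = balance_augment(segset, plan)
        b = [s for s in out if s.activity_id == "B"]
        assert len(b) == 3
        original = next(s for s in b if s.source_id == "original")
        for s in b:
            assert np.array_equal(s.samples, original.samples)

    def test_target_below_max_count_rejected(self):
        segset = make_segments({"A": 5, "B": 2})
        with pytest.raises(ValueError, match="below"):
            balance_augment(segset, AugmentationPlan(A=4))

    def test_composition_source_id(self):
        segset = make_segments({"A": 2, "B": 1})
        plan = AugmentationPlan(A=2, types=(("mw", "tw"),), seed=0)
        out = balance_augment(segset, plan)
        added = [s for s in out if s.source_id != "original"]
        assert [s.source_id for s in added] == ["mw+tw"]

    def test_deterministic_under_seed(self):
        segset = make_segments({"A": 4, "B": 1})
        p1 = balance_augment(segset, AugmentationPlan(A=4, types=("tw",), seed=9))
        p2 = balance_augment(segset, AugmentationPlan(A=4, types=("tw",), seed=9))
        for a, b in zip(p1, p2):
            assert np.array_equal(a.samples, b.samples)

    def test_empty_class_impossible_by_construction(self):
        # grouping only sees present labels; a plan on an empty set fails
        from nursehar.datamodel import SegmentSet
        with pytest.raises(ValueError):
            balance_augment(SegmentSet(), AugmentationPlan(A=1))
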