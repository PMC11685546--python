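"""Filtering, the 13-column IFS, MSUM and the 117-value FFS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nursehar.augment import rotation
from nursehar.features import (FEATURE_NAMES, IFS_COLUMNS,
                               NyquistWarning, build_feature_table,
                               butterworth_lowpass, compute_angles,
                               compute_ffs, compute_ifs, compute_magnitude,
                               integrate, median_filter, msum)
from conftest import make_segments
from oracles import brute_force_msum, butterworth_gain


class TestMedianFilter:
    def test_removes_isolated_spike(self):
        out = median_filter(np.array([0.0, 0, 9, 0, 0]), 5)
        assert out[2] == 0.0

    def test_constant_unchanged(self):
        x = np.full(30, 3.2)
        assert np.array_equal(median_filter(x, 5), x)

    def test_window_one_identity(self, rng):
        x = rng.normal(size=25)
        assert np.array_equal(median_filter(x, 1), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros(10), 4)

    def test_length_preserved_with_edge_shrink(self, rng):
        x = rng.normal(size=7)
        out = median_filter(x, 5)
        assert len(out) == 7
        assert out[0] == np.median(x[:3])  # shrunk edge window


class TestButterworth:
    def test_dc_gain_one(self):
        x = np.full(200, 2.5)
        out = butterworth_lowpass(x, fs=60.0)
        assert np.allclose(out, x, atol=1e-9)

    def test_sine_attenuation_matches_analytic_response(self):
        fs, f = 60.0, 25.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * f * t)
        out = butterworth_lowpass(x, fs=fs, cutoff=20.0, order=3)
        core = slice(500, 2500)  # avoid transient edges
        ratio = np.sqrt(np.mean(out[core] ** 2) / np.mean(x[core] ** 2))
        expected = butterworth_gain(f, 20.0, 3, fs_hz=fs) ** 2  # two passes
        assert abs(ratio - expected) / expected < 0.05

    def test_cutoff_above_nyquist_skips_with_warning(self):
        x = np.sin(np.arange(40))
        with pytest.warns(NyquistWarning):
            out = butterworth_lowpass(x, fs=4.0, cutoff=20.0)
        assert np.array_equal(out, x)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(np.array([1.0, np.inf, 2.0]), fs=60.0)


class TestMagnitudeAndAngles:
    def test_pythagorean_quadruple(self):
        assert compute_magnitude(np.array([[3.0, 4.0, 12.0]]))[0] == 13.0

    def test_zero_vector(self):
        assert compute_magnitude(np.zeros((1, 3)))[0] == 0.0

    def test_rotation_leaves_magnitude(self, segment):
        rotated = rotation(segment, np.random.default_rng(0))
        assert np.allclose(compute_magnitude(segment.samples),
                           compute_magnitude(rotated.samples), atol=1e-9)

    @pytest.mark.parametrize("sample,expected_z", [
        ((0.0, 0.0, 1.0), np.pi / 2),
        ((1.0, 1.0, np.sqrt(2.0)), np.pi / 4),
        ((1.0, 0.0, 0.0), 0.0),
    ])
    def test_angle_worked_cases(self, sample, expected_z):
        ang = compute_angles(np.array([sample]))
        assert ang[0, 2] == pytest.approx(expected_z, abs=1e-12)

    def test_all_zero_sample_maps_to_zero(self):
        assert np.array_equal(compute_angles(np.zeros((1, 3))), np.zeros((1, 3)))

    def test_angle_range(self, rng):
        ang = compute_angles(rng.normal(size=(500, 3)))
        assert np.all(ang > -np.pi / 2 - 1e-12)
        assert np.all(ang <= np.pi / 2 + 1e-12)


class TestIntegrate:
    def test_constant_first_order(self):
        out = integrate(np.ones(5), dt=1.0, order=1)
        assert np.allclose(out, [0, 1, 2, 3, 4])

    def test_zeros_both_orders(self):
        for order in (1, 2):
            assert np.array_equal(integrate(np.zeros(10), 0.1, order),
                                  np.zeros(10))

    def test_constant_second_order_closed_form(self):
        # acceleration a=2, dt=0.5: trapezoid reproduces t^2 * a / 2 exactly
        out = integrate(np.full(9, 2.0), dt=0.5, order=2)
        n = np.arange(9)
        assert np.allclose(out, n ** 2 * 0.25, atol=1e-9)


class TestIFS:
    def test_thirteen_columns_of_segment_length(self, segment):
        ifs = compute_ifs(segment)
        assert ifs.data.shape == (len(segment), 13)
        assert len(IFS_COLUMNS) == 13

    def test_zero_segment_all_zero(self):
        seg = make_segments({"A": 1})[0].with_samples(np.zeros((60, 3)))
        ifs = compute_ifs(seg)
        assert np.array_equal(ifs.data, np.zeros((60, 13)))

    def test_column_order_contract(self):
        assert IFS_COLUMNS[:4] == ("ax", "ay", "az", "magnitude")
        assert IFS_COLUMNS[4:7] == ("disp_x", "disp_y", "disp_z")
        assert IFS_COLUMNS[7:10] == ("vel_x", "vel_y", "vel_z")
        assert IFS_COLUMNS[10:] == ("angle_x", "angle_y", "angle_z")


class TestMsum:
    def test_monotone_series_is_zero(self):
        assert msum(np.arange(50.0)) == 0.0
        assert msum(-np.arange(50.0)) == 0.0

    def test_worked_series_matches_oracle(self):
        x = np.array([0.0, 2, 0, 3, 0, 4, 0, 5, 0])
        assert msum(x) == brute_force_msum(x)
        assert msum(x) == pytest.approx(3.5)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=200)
        assert msum(x) == pytest.approx(msum(x + 17.3), abs=1e-9)

    def test_agreement_with_oracle_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(50, 501))
            x = rng.normal(size=n)
            assert msum(x) == brute_force_msum(x)

    @given(st.lists(st.integers(min_value=-5, max_value=5),
                    min_size=2, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_oracle_agreement_with_ties_and_plateaus(self, values):
        x = np.array(values, dtype=float)
        assert msum(x) == brute_force_msum(x)


class TestFFS:
    def test_constant_column_statistics(self):
        seg = make_segments({"A": 1})[0].with_samples(np.full((60, 3), 2.0))
        ffs = compute_ffs(compute_ifs(seg))
        assert ffs["ax_sd"] == 0.0
        assert ffs["ax_avg"] == 2.0
        assert ffs["ax_max"] == ffs["ax_min"] == 2.0
        assert ffs["ax_var"] == ffs["ax_mad"] == ffs["ax_msum"] == 0.0
        assert ffs["ax_energy"] == 4.0
        assert ffs["ax_iqr"] == 0.0

    def test_vector_length_117(self, segment):
        ffs = compute_ffs(compute_ifs(segment))
        assert len(ffs) == 117
        assert len(FEATURE_NAMES) == 117
        assert len(set(FEATURE_NAMES)) == 117

    def test_var_equals_sd_squared(self, segment):
        ffs = compute_ffs(compute_ifs(segment))
        for col in IFS_COLUMNS:
            assert ffs[f"{col}_var"] == pytest.approx(
                ffs[f"{col}_sd"] ** 2, abs=1e-9)

    def test_hand_computed_column(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        from nursehar.features import _iqr, _mad
        assert _iqr(x) == pytest.approx(1.5)  # Q3=3.25, Q1=1.75
        assert _mad(x) == pytest.approx(1.0)
        assert np.mean(x ** 2) == pytest.approx(7.5)

    def test_scale_equivariance(self, segment):
        s = -2.5
        scaled = segment.with_samples(segment.samples * s)
        a = compute_ffs(compute_ifs(segment))
        b = compute_ffs(compute_ifs(scaled))
        for col in ("ax", "ay", "az", "magnitude"):
            factor = abs(s) if col == "magnitude" else s
            assert b[f"{col}_avg"] == pytest.approx(factor * a[f"{col}_avg"],
                                                    rel=1e-9, abs=1e-12)
            for stat in ("sd", "mad", "msum", "iqr"):
                assert b[f"{col}_{stat}"] == pytest.approx(
                    abs(s) * a[f"{col}_{stat}"], rel=1e-9, abs=1e-12)
            for stat in ("var", "energy"):
                assert b[f"{col}_{stat}"] == pytest.approx(
                    s * s * a[f"{col}_{stat}"], rel=1e-9, abs=1e-12)

    def test_rotation_invariance_of_magnitude_statistics(self, segment):
        rotated = rotation(segment, np.random.default_rng(6))
        a = compute_ffs(compute_ifs(segment))
        b = compute_ffs(compute_ifs(rotated))
        for stat in ("sd", "avg", "max", "min", "var", "mad", "msum",
                     "energy", "iqr"):
            assert b[f"magnitude_{stat}"] == pytest.approx(
                a[f"magnitude_{stat}"], abs=1e-9)


class TestBuildFeatureTable:
    def test_shape_and_completeness(self, small_dataset):
        table = build_feature_table(small_dataset)
        assert table.shape == (len(small_dataset), 120)  # 117 + 3 labels
        assert not table.isna().any().any()

    def test_deterministic(self, small_dataset):
        a = build_feature_table(small_dataset)
        b = build_feature_table(small_dataset)
        assert a.equals(b)

    def test_max_min_ordering(self, segment):
        ffs = compute_ffs(compute_ifs(segment))
        for col in IFS_COLUMNS:
            assert ffs[f"{col}_max"] >= ffs[f"{col}_min"]
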