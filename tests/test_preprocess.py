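"""Pre-processing chain: subtraction, smoothing, normalization, truncation, split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import teafluor as tf
from teafluor.errors import DegenerateSpectrumError, FormatError, ParameterError
from teafluor.preprocess import (
    normalize_to_chl_peak,
    smooth_sg,
    split_dataset,
    subtract_background,
    truncate_to_window,
)
from teafluor.synthetic import NoiseModel, RawMeasurement, simulate_measurement

from conftest import make_profile


def brute_force_savgol(y, window, order):
    """Independent oracle: explicit sliding least-squares polynomial fit."""
    half = window // 2
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if i < half:
            lo, hi = 0, window
        elif i >= n - half:
            lo, hi = n - window, n
        x = np.arange(lo, hi) - i
        coeffs = np.polyfit(x, y[lo:hi], order)
        out[i] = np.polyval(coeffs, 0.0)
    return out


class TestSubtractBackground:
    def test_self_subtraction_gives_zeros(self, grid):
        rows = np.tile(np.linspace(1, 2, grid.n_points), (8, 1))
        raw = RawMeasurement(grid=grid, rows=rows, label="G-V")
        assert np.array_equal(subtract_background(raw), np.zeros((7, grid.n_points)))

    def test_zero_background_leaves_rows_unchanged(self, grid):
        rng = np.random.default_rng(0)
        rows = rng.uniform(0, 1, (8, grid.n_points))
        rows[7] = 0.0
        raw = RawMeasurement(grid=grid, rows=rows, label="G-V")
        assert np.array_equal(subtract_background(raw), rows[:7])

    def test_spike_additivity(self, grid):
        bg = np.linspace(0.2, 0.4, grid.n_points)
        spike = np.zeros(grid.n_points)
        spike[grid.index_nearest(680.0)] = 1.0
        rows = np.tile(bg, (8, 1))
        rows[0] = bg + spike
        raw = RawMeasurement(grid=grid, rows=rows, label="G-V")
        assert np.allclose(subtract_background(raw)[0], spike)

    def test_wrong_row_count_rejected_at_construction(self, grid):
        from teafluor.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            RawMeasurement(grid=grid, rows=np.zeros((6, grid.n_points)), label="x")


class TestSavitzkyGolay:
    @given(c2=st.floats(-2, 2), c1=st.floats(-2, 2), c0=st.floats(-2, 2))
    @settings(max_examples=25, deadline=None)
    def test_reproduces_quadratics_exactly(self, c2, c1, c0):
        i = np.arange(60, dtype=float)
        y = c2 * i**2 + c1 * i + c0
        out = smooth_sg(y, 11, 2)
        assert np.allclose(out[5:-5], y[5:-5], atol=1e-8 * max(1.0, np.abs(y).max()))

    def test_constant_preserved(self):
        y = np.full(50, 3.7)
        assert np.allclose(smooth_sg(y, 11, 2), y)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=101)
        ours = smooth_sg(y, 11, 2)
        oracle = brute_force_savgol(y, 11, 2)
        assert np.max(np.abs(ours - oracle)) <= 1e-10 * max(1.0, np.abs(oracle).max())

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_sg(np.zeros(50), 10, 2)

    def test_window_not_exceeding_order_rejected(self):
        with pytest.raises(ParameterError):
            smooth_sg(np.zeros(50), 3, 3)


class TestNormalize:
    def test_divides_by_region_maximum(self, grid):
        y = np.ones(grid.n_points)
        y[grid.index_nearest(680.0)] = 5.0
        out = normalize_to_chl_peak(y, grid)
        assert out[grid.index_nearest(680.0)] == pytest.approx(1.0)
        assert np.allclose(np.delete(out, grid.index_nearest(680.0)), 0.2)

    def test_scale_invariance(self, grid):
        rng = np.random.default_rng(2)
        y = rng.uniform(0.1, 1.0, grid.n_points)
        assert np.allclose(normalize_to_chl_peak(3.5 * y, grid), normalize_to_chl_peak(y, grid))

    def test_idempotence(self, grid):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.1, 1.0, grid.n_points)
        once = normalize_to_chl_peak(y, grid)
        assert np.allclose(normalize_to_chl_peak(once, grid), once)

    def test_degenerate_spectrum_carries_id(self, grid):
        with pytest.raises(DegenerateSpectrumError) as exc:
            normalize_to_chl_peak(np.zeros(grid.n_points), grid, measurement_id="m-17")
        assert exc.value.measurement_id == "m-17"


class TestTruncate:
    def test_window_endpoints_and_length(self, grid):
        out = truncate_to_window(grid.wavelengths, grid)
        assert len(out) == 837
        assert out[0] == pytest.approx(500.0, abs=1e-9)
        assert out[-1] == pytest.approx(900.0, abs=1e-9)

    def test_slicing_consistency(self, grid):
        rng = np.random.default_rng(4)
        y = rng.normal(size=grid.n_points)
        whole = truncate_to_window(y, grid)
        idx = grid.window_indices()
        parts = [y[idx[:300]], y[idx[300:700]], y[idx[700:]]]
        assert np.array_equal(np.concatenate(parts), whole)

    def test_mismatched_grid_rejected(self):
        bad = tf.WavelengthGrid(start_nm=500.0, end_nm=900.0, step_nm=1.0)
        with pytest.raises(Exception):
            truncate_to_window(np.zeros(bad.n_points), bad)


class TestPipeline:
    def test_output_shape_7x837(self, small_dataset):
        mat = tf.preprocess_measurement(small_dataset[0])
        assert mat.values.shape == (7, 837)

    def test_every_row_peaks_at_one_in_red_region(self, small_matrices):
        for mat in small_matrices[:10]:
            sub = mat.values[:, (mat.wavelengths >= 650) & (mat.wavelengths <= 700)]
            assert np.allclose(sub.max(axis=1), 1.0, atol=1e-9)

    def test_green_class_far_red_above_threshold_noise_free(self, grid, leds, quiet_noise):
        profile = make_profile(label="G-LJ1", fr_amp=0.78, cv=0.0)
        raw = simulate_measurement(profile, leds, grid, quiet_noise, np.random.default_rng(0))
        mat = tf.preprocess_measurement(raw)
        col = np.argmin(np.abs(mat.wavelengths - 740.0))
        assert mat.values[0, col] > 0.6

    def test_normalization_applied_after_smoothing(self, grid, leds):
        # a narrow spike in the red region is attenuated by the smoother; if
        # normalization ran first, the smoothed output's red-region max would
        # fall below 1 — the pipeline must renormalize after smoothing
        rows = np.zeros((8, grid.n_points))
        spike = np.zeros(grid.n_points)
        spike[grid.index_nearest(680.0)] = 1.0
        rows[:7] = 0.05 + spike  # constant floor keeps normalization well-posed
        raw = RawMeasurement(grid=grid, rows=rows, label="G-V")
        mat = tf.preprocess_measurement(raw)
        region = mat.values[:, (mat.wavelengths >= 650) & (mat.wavelengths <= 700)]
        smoothed_spike_max = region.max()
        assert smoothed_spike_max == pytest.approx(1.0, abs=1e-9)
        # sanity: smoothing really did attenuate the raw spike
        assert tf.preprocess.smooth_sg(rows[0], 11, 2).max() < 0.9

    def test_pipeline_idempotent_on_interior(self, grid, leds, quiet_noise):
        profile = make_profile(cv=0.0)
        raw = simulate_measurement(profile, leds, grid, quiet_noise, np.random.default_rng(0))
        first = tf.preprocess_measurement(raw)
        # feed the smoothed+normalized full-grid spectra back with a zero background
        corrected = tf.preprocess.subtract_background(raw)
        smoothed = tf.preprocess.smooth_sg(corrected)
        normalized = np.stack([normalize_to_chl_peak(r, grid) for r in smoothed])
        again = RawMeasurement(grid=grid, rows=np.vstack([np.clip(normalized, 0, None),
                                                          np.zeros(grid.n_points)]), label="x")
        second = tf.preprocess_measurement(again)
        interior = slice(10, -10)
        assert np.max(np.abs(second.values[:, interior] - first.values[:, interior])) < 1e-3


class TestSplit:
    def test_half_split_counts(self, small_matrices):
        train, test = split_dataset(small_matrices, fraction=0.5, seed=0)
        assert len(train) == len(test) == len(small_matrices) // 2
        for label in {m.label for m in small_matrices}:
            assert sum(m.label == label for m in train) == 3
            assert sum(m.label == label for m in test) == 3

    def test_disjoint_union(self, small_matrices):
        train, test = split_dataset(small_matrices, fraction=0.5, seed=0)
        ids = lambda ms: sorted(id(m) for m in ms)
        assert sorted(ids(train) + ids(test)) == ids(small_matrices)

    def test_same_seed_same_split(self, small_matrices):
        a = split_dataset(small_matrices, seed=11)
        b = split_dataset(small_matrices, seed=11)
        assert [m.label for m in a[0]] == [m.label for m in b[0]]
        assert all(x is y for x, y in zip(a[0], b[0]))

    def test_single_sample_class_rejected(self, small_matrices):
        with pytest.raises(ParameterError):
            split_dataset(small_matrices[:1])
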