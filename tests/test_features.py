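"""Time-domain feature extraction: closed-form examples, AR oracle,
windowing arithmetic and scale/sign invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from semgsel import (FEATURE_NAMES, DegenerateWindowError, Recording,
                     WindowSpec, build_feature_matrix,
                     extract_window_features, windowize)
from semgsel.features import (_batch_features, ar_coefficients,
                              window_starts, zero_crossings)

TINY = WindowSpec(length=3, step=1, zc_threshold=10.0, ar_order=1)


def idx(name):
    return FEATURE_NAMES.index(name)


class TestScalarFeatures:
    def test_closed_form_small_window(self):
        f = extract_window_features([1, -2, 3], TINY)
        assert f[idx("IAV")] == 6
        assert f[idx("SSI")] == 14
        assert f[idx("WL")] == 8          # |-3| + |5|
        assert f[idx("ZC")] == 0          # gaps 3 and 5 below T=10
        assert f[idx("RMS")] == pytest.approx(np.sqrt(14 / 3))

    def test_zero_crossing_needs_sign_change_and_gap(self):
        assert zero_crossings(np.array([20., -20., 20., -20.]), 10.0) == 3
        assert zero_crossings(np.array([1., -2., 3.]), 0.0) == 2
        # same-sign neighbours never count, whatever the gap
        assert zero_crossings(np.array([1., 30., 1.]), 10.0) == 0

    def test_constant_window_is_degenerate(self):
        with pytest.raises(DegenerateWindowError):
            extract_window_features([5.0] * 3, TINY)

    def test_constant_window_scalar_parts_via_batch(self):
        vals = _batch_features(np.full((1, 8), 5.0),
                               WindowSpec(length=8, step=1))
        assert vals[0, idx("WL")] == 0
        assert vals[0, idx("ZC")] == 0
        assert vals[0, idx("RMS")] == pytest.approx(5.0)
        assert np.isnan(vals[0, idx("Kurtosis")])
        assert np.isnan(vals[0, idx("Skewness")])

    def test_window_length_mismatch(self):
        with pytest.raises(ValueError):
            extract_window_features([1.0, 2.0], TINY)


class TestAutoregressive:
    def test_matches_normal_equations_oracle(self, rng):
        # AR(4) realization; oracle = lstsq of x_i on its 4 lags
        a_true = np.array([1.456, -1.17, 0.524, -0.2916])
        x = np.zeros(256 + 100)
        eps = rng.standard_normal(len(x))
        for i in range(4, len(x)):
            x[i] = a_true @ x[i - 4:i][::-1] + eps[i]
        x = x[100:]
        Z = np.column_stack([x[3:-1], x[2:-2], x[1:-3], x[0:-4]])
        oracle = np.linalg.lstsq(Z, x[4:], rcond=None)[0]
        est = ar_coefficients(x, 4)
        assert est == pytest.approx(oracle, abs=1e-9)

    def test_converges_to_generating_coefficients(self, rng):
        a_true = np.array([1.456, -1.17, 0.524, -0.2916])
        x = np.zeros(4096 + 500)
        eps = rng.standard_normal(len(x))
        for i in range(4, len(x)):
            x[i] = a_true @ x[i - 4:i][::-1] + eps[i]
        est = ar_coefficients(x[500:], 4)
        assert est == pytest.approx(a_true, abs=0.1)

    def test_batch_matches_scalar_path(self, rng):
        spec = WindowSpec(length=64, step=32)
        wins = rng.standard_normal((5, 64))
        batch = _batch_features(wins, spec)
        for i in range(5):
            scalar = extract_window_features(wins[i], spec)
            assert batch[i] == pytest.approx(scalar, rel=1e-10)


class TestWindowing:
    @pytest.mark.parametrize("n,length,step,expected", [
        (1000, 200, 100, 9),
        (300, 300, 100, 1),
        (1000, 100, 150, 7),   # gaps between windows
    ])
    def test_window_count(self, n, length, step, expected):
        assert len(window_starts(n, WindowSpec(length=length, step=step))) \
            == expected

    def test_windows_respect_segments(self):
        rec = Recording(samples=np.arange(400.0)[:, None],
                        sampling_rate=100.0,
                        labels=np.repeat([1, 2], 200),
                        segments=np.repeat([0, 1], 200))
        spec = WindowSpec(length=150, step=50, ar_order=1)
        wins = windowize(rec, spec)
        # 2 windows per 200-sample segment, none straddling the boundary
        assert len(wins) == 4
        assert [lab for _, lab in wins] == [1, 1, 2, 2]

    def test_majority_label_and_transition_drop(self):
        labels = np.array([1] * 120 + [2] * 80)
        rec = Recording(samples=np.sin(np.arange(200.0))[:, None],
                        sampling_rate=100.0, labels=labels)
        spec = WindowSpec(length=200, step=200, ar_order=1)
        (_, lab), = windowize(rec, spec)
        assert lab == 1
        with pytest.raises(ValueError):
            windowize(rec, spec, drop_transition=True)

    def test_empty_recording_errors(self):
        rec = Recording(samples=np.zeros((50, 1)), sampling_rate=1.0,
                        labels=np.zeros(50))
        with pytest.raises(ValueError):
            windowize(rec, WindowSpec(length=100, step=10))


class TestFeatureMatrix:
    def test_dimensions_and_order(self, small_features):
        fm = small_features
        assert fm.d == 8 * 11 == 88
        assert fm.row_index[0] == (1, "WL")
        assert fm.row_index[11] == (2, "WL")
        assert fm.row_index[10] == (1, "AR4")
        assert len(fm.col_labels) == fm.n_windows

    def test_two_channels_give_22_rows(self, rng):
        rec = Recording(samples=rng.standard_normal((1000, 2)),
                        sampling_rate=1000.0, labels=np.ones(1000))
        fm = build_feature_matrix(rec, WindowSpec())
        assert fm.d == 22
        assert fm.n_windows == 9

    def test_standardized_rows_are_zscored(self, small_features):
        std = small_features.standardize()
        assert np.allclose(std.values.mean(axis=1), 0, atol=1e-9)
        sds = std.values.std(axis=1, ddof=1)
        live = np.asarray(small_features.values.std(axis=1, ddof=1)) > 0
        assert np.allclose(sds[live], 1, atol=1e-9)

    def test_subset_restricts_rows(self, small_features):
        sub = small_features.subset(channels={2, 4}, features={"WL", "RMS"})
        assert set(sub.row_index) == {(2, "WL"), (2, "RMS"),
                                      (4, "WL"), (4, "RMS")}


finite_windows = arrays(
    np.float64, st.integers(min_value=8, max_value=40),
    elements=st.floats(-1e3, 1e3, allow_nan=False)).filter(
        lambda w: np.std(w, ddof=1) > 1e-6)


class TestInvariants:
    @given(w=finite_windows)
    def test_sign_flip_invariance(self, w):
        spec = WindowSpec(length=len(w), step=1)
        f = extract_window_features(w, spec)
        g = extract_window_features(-w, spec)
        for name in ("WL", "IAV", "RMS", "SSI", "ZC", "Kurtosis"):
            assert g[idx(name)] == pytest.approx(f[idx(name)], rel=1e-9)

    @given(w=finite_windows, k=st.floats(0.1, 50.0))
    def test_positive_scaling(self, w, k):
        spec = WindowSpec(length=len(w), step=1, zc_threshold=0.0)
        f = extract_window_features(w, spec)
        g = extract_window_features(k * w, spec)
        for name in ("WL", "IAV", "RMS"):
            assert g[idx(name)] == pytest.approx(k * f[idx(name)],
                                                 rel=1e-6)
        assert g[idx("SSI")] == pytest.approx(k * k * f[idx("SSI")],
                                              rel=1e-6)
        for name in ("Kurtosis", "Skewness"):
            assert g[idx(name)] == pytest.approx(f[idx(name)], rel=1e-5,
                                                 abs=1e-7)

    @given(w=finite_windows)
    def test_ssi_equals_L_rms_squared(self, w):
        spec = WindowSpec(length=len(w), step=1)
        f = extract_window_features(w, spec)
        assert f[idx("SSI")] == pytest.approx(
            len(w) * f[idx("RMS")] ** 2, rel=1e-9)

    @given(w=finite_windows)
    def test_nonnegative_magnitude_features(self, w):
        spec = WindowSpec(length=len(w), step=1)
        f = extract_window_features(w, spec)
        for name in ("WL", "IAV", "RMS", "SSI", "ZC"):
            assert f[idx(name)] >= 0
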