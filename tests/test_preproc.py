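"""Preprocessing operators: exact contracts and least-squares oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripledfc.core import BoldImage
from tripledfc import preproc
from tests.conftest import random_bold


class TestDiscard:
    def test_240_minus_10_gives_230(self, rng):
        img = random_bold(rng, n_volumes=240)
        out = preproc.discard_initial_volumes(img, 10)
        assert out.n_volumes == 230
        np.testing.assert_array_equal(out.data, img.data[..., 10:])
        np.testing.assert_array_equal(out.affine, img.affine)

    def test_zero_is_identity(self, rng):
        img = random_bold(rng, n_volumes=20)
        np.testing.assert_array_equal(
            preproc.discard_initial_volumes(img, 0).data, img.data)

    def test_emptying_forbidden(self, rng):
        img = random_bold(rng, n_volumes=5)
        with pytest.raises(ValueError):
            preproc.discard_initial_volumes(img, 5)


class TestMotionExclusion:
    def test_no_motion_not_excluded(self):
        assert preproc.exclude_by_motion(np.zeros((50, 6))) is False

    def test_single_axis_over_3mm_excluded(self):
        trace = np.zeros((50, 6))
        trace[30:, 1] = 3.5
        assert preproc.exclude_by_motion(trace) is True

    def test_just_under_both_limits_kept(self):
        trace = np.zeros((50, 6))
        trace[:, 0] = np.linspace(0, 2.9, 50)   # translation, mm
        trace[:, 4] = np.linspace(0, -2.9, 50)  # rotation, degrees
        assert preproc.exclude_by_motion(trace) is False

    def test_displacement_relative_to_first_volume(self):
        # constant large offset but no movement: not excluded
        trace = np.full((20, 6), 5.0)
        assert preproc.exclude_by_motion(trace) is False


class TestFriston24:
    def test_zero_motion_gives_zero_matrix(self):
        out = preproc.friston24(np.zeros((30, 6)))
        assert out.shape == (30, 24)
        assert not out.any()

    def test_squared_column_is_elementwise_square(self):
        t = np.arange(30, dtype=float)
        motion = np.zeros((30, 6))
        motion[:, 2] = t
        out = preproc.friston24(motion)
        np.testing.assert_allclose(out[:, 12 + 2], t ** 2)

    def test_matches_per_element_construction(self, rng):
        motion = rng.standard_normal((25, 6))
        out = preproc.friston24(motion)
        expected = np.zeros((25, 24))
        for t in range(25):
            for j in range(6):
                prev = motion[t - 1, j] if t > 0 else 0.0
                expected[t, j] = motion[t, j]
                expected[t, 6 + j] = prev
                expected[t, 12 + j] = motion[t, j] ** 2
                expected[t, 18 + j] = prev ** 2
        np.testing.assert_allclose(out, expected)


class TestNuisanceRegression:
    def test_regressor_itself_reduces_to_zero(self, rng):
        nuis = rng.standard_normal((50, 3))
        resid = preproc.regress_nuisance(nuis[:, 1].copy(), nuis)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        ts = rng.standard_normal((40, 5))
        nuis = rng.standard_normal((40, 4))
        resid = preproc.regress_nuisance(ts, nuis)
        X = np.column_stack([np.ones(40), nuis])
        beta = np.linalg.solve(X.T @ X, X.T @ ts)
        np.testing.assert_allclose(resid, ts - X @ beta, atol=1e-8)
        # residuals orthogonal to every regressor
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_collinear_columns_dropped_with_warning(self, rng):
        nuis = rng.standard_normal((30, 2))
        nuis = np.column_stack([nuis, nuis[:, 0] * 2.0])
        with pytest.warns(UserWarning, match="collinear"):
            resid = preproc.regress_nuisance(rng.standard_normal(30), nuis)
        assert np.isfinite(resid).all()


class TestBandpass:
    def test_stopband_attenuated(self):
        t = np.arange(230) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)  # 0.2 Hz, above the 0.08 Hz edge
        y = preproc.bandpass(x, tr=2.0)
        assert (y ** 2).sum() < 0.01 * (x ** 2).sum()

    def test_passband_preserved(self):
        t = np.arange(230) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = preproc.bandpass(x, tr=2.0)
        assert abs((y ** 2).sum() / (x ** 2).sum() - 1.0) < 0.01

    def test_constant_series_zeroed(self):
        np.testing.assert_allclose(preproc.bandpass(np.full(100, 7.0), 2.0),
                                   0.0, atol=1e-10)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            preproc.bandpass(np.random.default_rng(0).standard_normal(50),
                             tr=2.0, low=0.01, high=0.4)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        img = random_bold(rng, n_volumes=5)
        assert preproc.smooth_gaussian(img, 0.0) is img

    def test_constant_volume_unchanged(self):
        affine = np.eye(4) * 3.0
        affine[3, 3] = 1.0
        img = BoldImage(np.full((8, 8, 8, 2), 3.3), affine, 2.0)
        out = preproc.smooth_gaussian(img, 6.0)
        interior = out.data[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(interior, 3.3, rtol=1e-6)

    def test_impulse_half_maximum_at_half_fwhm(self):
        # a 6-mm FWHM kernel on a 3-mm grid: the voxel 3 mm from the peak
        # sits at the half-maximum contour
        affine = np.eye(4) * 3.0
        affine[3, 3] = 1.0
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 1.0
        out = preproc.smooth_gaussian(BoldImage(data, affine, 2.0), 6.0).data
        ratio = out[8, 7, 7, 0] / out[7, 7, 7, 0]
        assert ratio == pytest.approx(0.5, abs=0.06)

    def test_total_intensity_conserved(self, rng):
        affine = np.eye(4) * 3.0
        affine[3, 3] = 1.0
        data = np.zeros((16, 16, 16, 1))
        data[6:10, 6:10, 6:10, 0] = rng.random((4, 4, 4))
        out = preproc.smooth_gaussian(BoldImage(data, affine, 2.0), 6.0).data
        assert out.sum() == pytest.approx(data.sum(), rel=1e-6)


class TestDetrend:
    def test_line_removed_exactly(self):
        t = np.arange(50, dtype=float)
        np.testing.assert_allclose(preproc.detrend_linear(3.0 + 0.5 * t), 0.0,
                                   atol=1e-10)

    def test_idempotent(self, rng):
        x = preproc.detrend_linear(rng.standard_normal(80))
        np.testing.assert_allclose(preproc.detrend_linear(x), x, atol=1e-10)

    def test_matches_least_squares_oracle(self, rng):
        x = rng.standard_normal(60)
        t = np.arange(60, dtype=float)
        X = np.column_stack([np.ones(60), t])
        beta = np.linalg.lstsq(X, x, rcond=None)[0]
        np.testing.assert_allclose(preproc.detrend_linear(x), x - X @ beta,
                                   atol=1e-10)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.floats(-3, 3), st.floats(-3, 3))
def test_temporal_operators_are_linear(seed, a, b):
    """detrend, band-pass and nuisance regression all commute with linear
    combinations of their inputs."""
    r = np.random.default_rng(seed)
    x, y = r.standard_normal(64), r.standard_normal(64)
    nuis = r.standard_normal((64, 3))
    for op in (preproc.detrend_linear,
               lambda v: preproc.bandpass(v, 2.0),
               lambda v: preproc.regress_nuisance(v, nuis)):
        lhs = op(a * x + b * y)
        rhs = a * op(x) + b * op(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_full_pipeline_runs_and_excludes(tiny_design):
    from tripledfc import synth
    img, motion, _ = synth.simulate_subject(tiny_design, "HC", 5)
    tissue = synth.tissue_masks(tiny_design)
    clean = preproc.preprocess_subject(img, motion, tissue)
    assert clean.n_volumes == 230
    bad = motion.copy()
    bad[200:, 0] += 10.0
    assert preproc.preprocess_subject(img, bad, tissue) is None
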