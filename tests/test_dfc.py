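"""Sliding-window bookkeeping, windowed correlation and variability."""

import numpy as np
import pytest

from tripledfc import dfc
from tripledfc.networks import R_CLIP
from tests.conftest import random_bold


class TestWindows:
    @pytest.mark.parametrize("T,width,step,expected_k", [
        (230, 40, 2, 96),   # the study conditions
        (40, 40, 2, 1),
        (44, 40, 2, 3),
        (100, 30, 7, 11),
    ])
    def test_window_count(self, T, width, step, expected_k):
        scheme = dfc.make_windows(T, width, step)
        assert scheme.n_windows == expected_k
        assert scheme.starts[0] == 0
        assert all(b - a == step for a, b in zip(scheme.starts,
                                                 scheme.starts[1:]))
        assert scheme.last_end <= T  # final window fits entirely

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            dfc.make_windows(39, 40, 2)


def _series_with_window_correlations(rng, scheme, rs):
    """Seed + voxel series whose per-window sample correlation is exactly
    rs[k], built by Gram-Schmidt within each (non-overlapping) window."""
    T = scheme.last_end
    s = rng.standard_normal(T)
    v = np.empty(T)
    for k, a in enumerate(scheme.starts):
        sl = slice(a, a + scheme.width)
        sw = s[sl] - s[sl].mean()
        e = rng.standard_normal(scheme.width)
        e -= e.mean()
        e -= (e @ sw) / (sw @ sw) * sw
        r = rs[k]
        v[sl] = r * sw / np.linalg.norm(sw) + \
            np.sqrt(1 - r ** 2) * e / np.linalg.norm(e)
    return s, v


class TestWindowedZ:
    def test_identical_series_hit_clip_ceiling(self, rng):
        scheme = dfc.make_windows(100, 20, 5)
        x = rng.standard_normal(100)
        z = dfc.windowed_z_series(x, x, scheme)
        np.testing.assert_allclose(z, np.arctanh(R_CLIP))

    def test_length_contract_and_small_z_for_noise(self, rng):
        scheme = dfc.make_windows(230, 40, 2)
        z = dfc.windowed_z_series(rng.standard_normal(230),
                                  rng.standard_normal(230), scheme)
        assert z.shape == (96,)
        assert np.abs(z).mean() < 0.5

    def test_constructed_alternating_correlations(self, rng):
        # non-overlapping windows with exact sample correlation +/-0.5
        scheme = dfc.make_windows(160, 40, 40)
        rs = [0.5, -0.5, 0.5, -0.5]
        s, v = _series_with_window_correlations(rng, scheme, rs)
        z = dfc.windowed_z_series(s, v, scheme)
        np.testing.assert_allclose(z, np.arctanh(rs), atol=1e-10)
        np.testing.assert_allclose(np.abs(z), 0.5493, atol=1e-4)

    def test_flat_window_flagged_zero(self, rng):
        scheme = dfc.make_windows(60, 20, 20)
        v = rng.standard_normal(60)
        v[20:40] = 3.14  # zero variance in the middle window
        z = dfc.windowed_z_series(rng.standard_normal(60), v, scheme)
        assert z[1] == 0.0


class TestVariability:
    def test_constant_series_zero(self):
        assert dfc.variability(np.full(96, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_closed_form(self):
        a = 0.5493
        K = 96
        z = a * (-1.0) ** np.arange(K)
        expected = a * np.sqrt(K / (K - 1))
        assert dfc.variability(z) == pytest.approx(expected, rel=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        z = rng.standard_normal(96)
        mean = sum(z) / len(z)
        oracle = np.sqrt(sum((x - mean) ** 2 for x in z) / (len(z) - 1))
        assert dfc.variability(z) == pytest.approx(oracle, abs=1e-12)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            dfc.variability(np.array([1.0]))


class TestVariabilityMap:
    def test_matches_naive_per_voxel_loop(self, rng):
        from tripledfc.synth import SeedSpec
        img = random_bold(rng, shape=(5, 5, 5), n_volumes=60)
        seed = SeedSpec("s", (6.0, 6.0, 6.0), 1.4)
        scheme = dfc.make_windows(60, 20, 4)
        vmap = dfc.variability_map(img, seed, scheme)
        seed_ts = img.data[2, 2, 2]
        for idx in [(0, 0, 0), (1, 2, 3), (4, 4, 4), (2, 2, 2)]:
            zs = []
            for a in scheme.starts:
                sl = slice(a, a + scheme.width)
                r = np.corrcoef(seed_ts[sl], img.data[idx][sl])[0, 1]
                zs.append(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
            assert vmap[idx] == pytest.approx(np.std(zs, ddof=1), abs=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        from tripledfc.synth import SeedSpec
        img = random_bold(rng, shape=(4, 4, 4), n_volumes=50)
        seed = SeedSpec("s", (3.0, 3.0, 3.0), 1.4)
        scheme = dfc.make_windows(50, 20, 5)
        m1 = dfc.variability_map(img, seed, scheme)
        img2 = img.with_data(3.7 * img.data + 11.0)
        m2 = dfc.variability_map(img2, seed, scheme)
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_time_reversal_invariance(self, rng):
        from tripledfc.synth import SeedSpec
        img = random_bold(rng, shape=(4, 4, 4), n_volumes=60)
        seed = SeedSpec("s", (3.0, 3.0, 3.0), 1.4)
        scheme = dfc.make_windows(60, 20, 20)  # windows tile the series
        m1 = dfc.variability_map(img, seed, scheme)
        m2 = dfc.variability_map(img.with_data(img.data[..., ::-1]), seed,
                                 scheme)
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_standardize_zscores_across_voxels(self, rng):
        from tripledfc.synth import SeedSpec
        img = random_bold(rng, shape=(5, 5, 5), n_volumes=60)
        seed = SeedSpec("s", (6.0, 6.0, 6.0), 1.4)
        scheme = dfc.make_windows(60, 20, 4)
        raw = dfc.variability_map(img, seed, scheme)
        std = dfc.variability_map(img, seed, scheme, standardize=True)
        assert std.mean() == pytest.approx(0.0, abs=1e-10)
        assert std[img.mask].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        # standardisation is monotone: voxel ordering is preserved
        assert (np.argsort(raw.ravel()) == np.argsort(std.ravel())).all()

    def test_wider_windows_reduce_stationary_variability(self):
        """For stationary correlated Gaussian pairs the expected windowed-z
        spread shrinks as the window widens (20 -> 40 -> 80 TRs)."""
        rng = np.random.default_rng(99)
        means = []
        for width in (20, 40, 80):
            scheme = dfc.make_windows(230, width, 2)
            sds = []
            for _ in range(40):
                s = rng.standard_normal(230)
                v = 0.5 * s + rng.standard_normal(230)
                sds.append(dfc.variability(dfc.windowed_z_series(s, v, scheme)))
            means.append(np.mean(sds))
        assert means[0] > means[1] > means[2]
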