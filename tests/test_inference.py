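"""Group inference: partial-F oracle, permutation clustering, post hoc,
and the demographic summary statistics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tripledfc import inference
from tripledfc.inference import (InferenceConfig, ancova_f_map,
                                 anova_from_summary, chisq_contingency,
                                 covariate_matrix, partial_f,
                                 permutation_cluster_threshold,
                                 posthoc_pairwise)


def _groups(n_per):
    return pd.Series(["HC"] * n_per + ["SCD"] * n_per + ["aMCI"] * n_per)


def _covars(rng, n):
    C = np.column_stack([rng.normal(64, 7, n), rng.integers(0, 2, n),
                         rng.normal(12, 3, n)])
    return C - C.mean(axis=0)


class TestPartialF:
    def test_matches_scalar_glm_oracle(self, rng):
        """Vectorised partial F equals per-voxel nested OLS fits."""
        n = 45
        g = _groups(15)
        C = _covars(rng, n)
        Y = rng.standard_normal((n, 5))
        d1 = (g == "SCD").to_numpy(float)
        d2 = (g == "aMCI").to_numpy(float)
        X_red = np.column_stack([np.ones(n), C])
        X_full = np.column_stack([X_red, d1, d2])
        F, df1, df2 = partial_f(Y, X_full, X_red)
        assert (df1, df2) == (2, n - 6)
        for v in range(5):
            full = sm.OLS(Y[:, v], X_full).fit()
            red = sm.OLS(Y[:, v], X_red).fit()
            oracle = ((red.ssr - full.ssr) / 2) / (full.ssr / (n - 6))
            assert F[v] == pytest.approx(oracle, abs=1e-8)

    def test_null_f_centered_near_one(self, rng):
        n = 300
        g = _groups(100)
        C = _covars(rng, n)
        Y = rng.standard_normal((n, 4000))
        X_red = np.column_stack([np.ones(n), C])
        d = np.column_stack([(g == "SCD").to_numpy(float),
                             (g == "aMCI").to_numpy(float)])
        F, _, df2 = partial_f(Y, np.column_stack([X_red, d]), X_red)
        assert np.mean(F) == pytest.approx(df2 / (df2 - 2), abs=0.05)

    def test_injected_effect_localised(self, rng):
        """A group mean shift confined to one region drives the max F there."""
        n_per, shape = 12, (8, 8, 8)
        g = _groups(n_per)
        maps = rng.standard_normal((3 * n_per, *shape))
        region = np.zeros(shape, dtype=bool)
        region[2:5, 2:5, 2:5] = True
        maps[np.asarray(g == "aMCI"), ...] += 1.5 * region
        C = _covars(rng, 3 * n_per)
        fmap = ancova_f_map(maps, g, C, np.ones(shape, dtype=bool))
        assert fmap[region].max() > fmap[~region].max()


class TestPermutationClustering:
    def test_extent_and_mm3_bookkeeping(self, rng):
        n_per, shape = 10, (10, 10, 10)
        g = _groups(n_per)
        maps = rng.standard_normal((3 * n_per, *shape))
        region = np.zeros(shape, dtype=bool)
        region[2:7, 2:7, 2:7] = True
        maps[np.asarray(g == "aMCI"), ...] += 2.0 * region
        C = _covars(rng, 3 * n_per)
        cfg = InferenceConfig(n_perm=99, ancova_min_voxels=20)
        affine = np.eye(4) * 3.0
        affine[3, 3] = 1.0
        table, extras = permutation_cluster_threshold(
            maps, g, C, np.ones(shape, dtype=bool), affine, 3.0, cfg,
            np.random.default_rng(0))
        assert len(table) >= 1
        assert (table["n_voxels"] >= 20).all()
        np.testing.assert_allclose(table["size_mm3"],
                                   table["n_voxels"] * 27.0)
        assert (table["p_corrected"] < 0.05).all()
        # the dominant cluster covers the injected region
        labels = table.attrs["labels"]
        top = table.sort_values("n_voxels").iloc[-1]
        assert ((labels == top.cluster_id) & region).sum() > 0.5 * region.sum()
        # peak coordinate lies inside its cluster
        ijk = np.linalg.inv(affine) @ np.r_[top.peak_x, top.peak_y, top.peak_z, 1]
        assert (labels == top.cluster_id)[tuple(np.round(ijk[:3]).astype(int))]

    def test_null_returns_empty_table(self, rng):
        n_per, shape = 8, (8, 8, 8)
        g = _groups(n_per)
        maps = rng.standard_normal((3 * n_per, *shape))
        C = _covars(rng, 3 * n_per)
        cfg = InferenceConfig(n_perm=99)
        affine = np.eye(4) * 3.0
        affine[3, 3] = 1.0
        table, _ = permutation_cluster_threshold(
            maps, g, C, np.ones(shape, dtype=bool), affine, 3.0, cfg,
            np.random.default_rng(1))
        assert isinstance(table, pd.DataFrame)  # empty result is permitted
        assert (table["n_voxels"] >= 20).all() if len(table) else True


class TestPosthoc:
    def _setup(self, rng, effect):
        n_per, shape = 12, (8, 8, 8)
        g = pd.Series(["HC"] * n_per + ["aMCI"] * n_per)
        maps = rng.standard_normal((2 * n_per, *shape))
        region = np.zeros(shape, dtype=bool)
        region[2:6, 2:6, 2:6] = True
        maps[n_per:] += effect * region
        C = _covars(rng, 2 * n_per)
        affine = np.eye(4) * 3.0
        affine[3, 3] = 1.0
        return g, maps, region, C, affine

    def test_detects_direction_and_extent(self, rng):
        g, maps, region, C, affine = self._setup(rng, 2.5)
        cfg = InferenceConfig(n_perm=99, posthoc_min_voxels=10)
        table, extras = posthoc_pairwise(
            maps, g, ("HC", "aMCI"), C, np.ones(region.shape, bool),
            affine, 3.0, cfg, np.random.default_rng(2))
        assert len(table) >= 1
        top = table.sort_values("n_voxels").iloc[-1]
        assert top.peak_stat > 0  # aMCI coded 1: positive t = aMCI > HC
        assert top.n_voxels >= 10 and top.size_mm3 == top.n_voxels * 27.0
        labels = table.attrs["labels"]
        assert ((labels == top.cluster_id) & region).any()

    def test_identical_groups_rarely_survive(self, rng):
        g, maps, region, C, affine = self._setup(rng, 0.0)
        cfg = InferenceConfig(n_perm=99)
        table, _ = posthoc_pairwise(
            maps, g, ("HC", "aMCI"), C, np.ones(region.shape, bool),
            affine, 3.0, cfg, np.random.default_rng(3))
        assert len(table) == 0

    def test_never_reports_outside_mask(self, rng):
        g, maps, region, C, affine = self._setup(rng, 2.5)
        cfg = InferenceConfig(n_perm=99, posthoc_min_voxels=1)
        table, extras = posthoc_pairwise(
            maps, g, ("HC", "aMCI"), C, region, affine, 3.0, cfg,
            np.random.default_rng(4))
        assert not (extras["supra"] & ~region).any()


class TestDemographicStats:
    def test_sex_by_group_chi2(self):
        chi2, df, p = chisq_contingency([[25, 8, 13], [33, 36, 36]])
        assert chi2 == pytest.approx(7.865, abs=1e-3)
        assert df == 2
        assert p == pytest.approx(0.020, abs=1e-3)

    def test_proportional_rows_zero(self):
        chi2, _, _ = chisq_contingency([[10, 20, 30], [5, 10, 15]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_definition(self, rng):
        table = rng.integers(5, 40, (2, 3)).astype(float)
        chi2, df, _ = chisq_contingency(table)
        E = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert chi2 == pytest.approx(((table - E) ** 2 / E).sum(), abs=1e-10)
        assert df == 2

    def test_age_rows_from_summary(self):
        F, df1, df2 = anova_from_summary([58, 44, 49],
                                         [63.328, 66.000, 63.633],
                                         [6.28, 7.80, 7.58])
        assert F == pytest.approx(1.966, abs=0.002)
        assert (df1, df2) == (2, 148)

    def test_equal_means_zero(self):
        F, _, _ = anova_from_summary([10, 12], [5.0, 5.0], [1.0, 2.0])
        assert F == 0.0

    def test_two_groups_equal_pooled_t_squared(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 25)
        F, _, _ = anova_from_summary([30, 25], [x.mean(), y.mean()],
                                     [x.std(ddof=1), y.std(ddof=1)])
        from scipy.stats import ttest_ind
        t, _ = ttest_ind(x, y)
        assert F == pytest.approx(t ** 2, rel=1e-10)
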