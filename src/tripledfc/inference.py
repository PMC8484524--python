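"""Voxel-wise group inference on DFC variability maps.

Three-group ANCOVA (HC / SCD / aMCI) with age, sex and education covariates,
assessed with Freedman-Lane permutations: the default path forms clusters at
a voxel-wise permutation p < 0.05 and corrects at cluster level against the
max-cluster-size null with a 20-voxel extent rule (540 mm^3 at 3 mm); a
TFCE-based path is also available.  Post-hoc pairwise comparisons run within
the ANCOVA mask with TFCE + max-statistic FWE and a > 9-voxel (243 mm^3)
extent rule.  Also provides the summary statistics used for demographic
tables (Pearson chi-squared, ANOVA from per-group summary rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from tripledfc.core import voxel_to_mm
from tripledfc.tfce import TFCEParams, tfce_transform, _structure


@dataclass
class InferenceConfig:
    n_perm: int = 1000
    voxel_alpha: float = 0.05        # cluster-forming threshold (ANCOVA path)
    cluster_alpha: float = 0.05      # corrected cluster-level alpha
    ancova_min_voxels: int = 20      # "cluster size >= 540 mm^3" at 3 mm
    posthoc_alpha: float = 0.05      # TFCE-FWE voxel alpha
    posthoc_min_voxels: int = 10     # "> 9 voxels", i.e. 270 mm^3 at 3 mm
    tfce: TFCEParams = field(default_factory=TFCEParams)

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("need at least 99 permutations")
        for a in (self.voxel_alpha, self.cluster_alpha, self.posthoc_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must be in (0, 1)")
        if self.ancova_min_voxels < 1 or self.posthoc_min_voxels < 1:
            raise ValueError("extent thresholds must be positive")


# ---------------------------------------------------------------- designs

def covariate_matrix(table: pd.DataFrame) -> np.ndarray:
    """Mean-centred age / sex / education covariate columns."""
    C = table[["age", "sex", "education"]].to_numpy(dtype=float)
    return C - C.mean(axis=0)


def group_dummies(groups: pd.Series | np.ndarray,
                  levels: tuple[str, ...] | None = None) -> np.ndarray:
    """Indicator columns for all but the first group level."""
    g = pd.Series(np.asarray(groups))
    levels = levels or tuple(pd.unique(g))
    return np.column_stack([(g == lv).to_numpy(float) for lv in levels[1:]])


def _rank(X: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(X))


def _prune_collinear(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return X[:, keep]


def _resid_maker(X: np.ndarray) -> np.ndarray:
    return np.eye(len(X)) - X @ np.linalg.pinv(X)


def partial_f(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray
              ) -> tuple[np.ndarray, int, int]:
    """Vectorised partial F for the columns of X_full beyond X_red.

    ``Y`` is ``(N, V)``.  Returns ``(F, df1, df2)``; zero-residual voxels
    get F = 0.
    """
    Mf, Mr = _resid_maker(X_full), _resid_maker(X_red)
    rss_f = ((Mf @ Y) ** 2).sum(axis=0)
    rss_r = ((Mr @ Y) ** 2).sum(axis=0)
    df1 = _rank(X_full) - _rank(X_red)
    df2 = Y.shape[0] - _rank(X_full)
    if df1 < 1 or df2 < 1:
        raise ValueError("design matrix leaves no degrees of freedom")
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return np.where(rss_f > 1e-300, np.clip(F, 0.0, None), 0.0), df1, df2


def ancova_f_map(maps: np.ndarray, groups, covariates: np.ndarray,
                 mask: np.ndarray) -> np.ndarray:
    """Voxel-wise partial F for the group factor, adjusted for covariates.

    ``maps`` is ``(N, X, Y, Z)``; the returned 3D map is zero outside
    ``mask``.
    """
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    g = pd.Series(np.asarray(groups))
    if g.nunique() < 3:
        raise ValueError("need all three groups represented")
    N = maps.shape[0]
    ones = np.ones((N, 1))
    X_red = _prune_collinear(np.hstack([ones, covariates]))
    X_full = _prune_collinear(np.hstack([X_red, group_dummies(g)]))
    Y = maps[:, mask]
    F, _, _ = partial_f(Y, X_full, X_red)
    out = np.zeros(mask.shape)
    out[mask] = F
    return out


# ------------------------------------------------- clusters and tables

def _cluster_table(supra: np.ndarray, stat3d: np.ndarray, affine: np.ndarray,
                   voxel_size_mm: float, connectivity: int = 26,
                   corrected_p=None) -> pd.DataFrame:
    """Label a suprathreshold mask and tabulate size / peak per cluster.

    Peak is the in-cluster voxel with maximum |stat|; ties break to the
    first voxel in lexicographic index order.
    """
    struct = _structure(supra.ndim, connectivity)
    labels, n = ndimage.label(supra, structure=struct)
    rows = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        vals = stat3d[tuple(idx.T)]
        peak_local = int(np.argmax(np.abs(vals)))
        peak_ijk = idx[peak_local]
        xyz = voxel_to_mm(affine, peak_ijk)[0]
        rows.append({
            "cluster_id": lab,
            "n_voxels": int(len(idx)),
            "size_mm3": float(len(idx) * voxel_size_mm ** 3),
            "peak_x": float(xyz[0]), "peak_y": float(xyz[1]),
            "peak_z": float(xyz[2]),
            "peak_stat": float(vals[peak_local]),
        })
    df = pd.DataFrame(rows, columns=["cluster_id", "n_voxels", "size_mm3",
                                     "peak_x", "peak_y", "peak_z", "peak_stat"])
    df.attrs["labels"] = labels
    return df


def cluster_voxels(table: pd.DataFrame, cluster_id: int) -> np.ndarray:
    """Boolean voxel mask of one cluster from a cluster table."""
    labels = table.attrs["labels"]
    return labels == cluster_id


def _max_cluster_size(supra: np.ndarray, struct: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=struct)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return int(sizes.max())


def permutation_cluster_threshold(maps: np.ndarray, groups,
                                  covariates: np.ndarray, mask: np.ndarray,
                                  affine: np.ndarray, voxel_size_mm: float,
                                  cfg: InferenceConfig,
                                  rng: np.random.Generator | None = None,
                                  use_tfce: bool = False
                                  ) -> tuple[pd.DataFrame, dict]:
    """ANCOVA with Freedman-Lane permutation and cluster-extent correction.

    Nuisance-only residuals are permuted, the group partial F recomputed,
    clusters formed at voxel-wise permutation p < ``voxel_alpha`` (or, with
    ``use_tfce``, at TFCE-FWE p < alpha), and cluster-level significance
    taken from the max-cluster-size null.  Clusters must also meet the
    extent rule (``ancova_min_voxels``).  An empty table is a valid result.
    """
    rng = rng or np.random.default_rng()
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    g = pd.Series(np.asarray(groups))
    N = maps.shape[0]
    ones = np.ones((N, 1))
    X_red = _prune_collinear(np.hstack([ones, covariates]))
    X_full = _prune_collinear(np.hstack([X_red, group_dummies(g)]))
    Y = maps[:, mask]
    V = Y.shape[1]
    struct = _structure(3, cfg.tfce.connectivity)

    F_obs, _, _ = partial_f(Y, X_full, X_red)

    # Freedman-Lane: permute reduced-model residuals
    H_red = X_red @ np.linalg.pinv(X_red)
    fitted = H_red @ Y
    resid = Y - fitted
    F_perm = np.empty((cfg.n_perm, V), dtype=np.float32)
    for i in range(cfg.n_perm):
        perm = rng.permutation(N)
        Fp, _, _ = partial_f(fitted + resid[perm], X_full, X_red)
        F_perm[i] = Fp

    if use_tfce:
        f3 = np.zeros(mask.shape)
        f3[mask] = F_obs
        tfce_obs = tfce_transform(f3, cfg.tfce)[mask]
        exceed = np.zeros(V)
        for i in range(cfg.n_perm):
            f3p = np.zeros(mask.shape)
            f3p[mask] = F_perm[i]
            exceed += tfce_transform(f3p, cfg.tfce).max() >= tfce_obs
        p_vox = (1.0 + exceed) / (cfg.n_perm + 1.0)
        supra_obs_flat = p_vox < cfg.voxel_alpha
        null_sizes = None
    else:
        # voxel-wise permutation p via ranks over {obs} U {perms}
        all_f = np.vstack([F_obs.astype(np.float32)[None, :], F_perm])
        ranks = stats.rankdata(all_f, axis=0, method="min")
        n_tot = cfg.n_perm + 1
        p_all = (n_tot + 1 - ranks) / n_tot  # P(value >= this) within the set
        supra_all = p_all < cfg.voxel_alpha
        supra_obs_flat = supra_all[0]
        null_sizes = np.empty(cfg.n_perm, dtype=int)
        buf = np.zeros(mask.shape, dtype=bool)
        for i in range(cfg.n_perm):
            buf[:] = False
            buf[mask] = supra_all[i + 1]
            null_sizes[i] = _max_cluster_size(buf, struct)

    f3 = np.zeros(mask.shape)
    f3[mask] = F_obs
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = supra_obs_flat
    table = _cluster_table(supra, f3, affine, voxel_size_mm,
                           cfg.tfce.connectivity)
    if null_sizes is not None and len(table):
        table["p_corrected"] = [
            float((1 + (null_sizes >= s).sum()) / (cfg.n_perm + 1))
            for s in table["n_voxels"]
        ]
        keep = (table["n_voxels"] >= cfg.ancova_min_voxels) & \
               (table["p_corrected"] < cfg.cluster_alpha)
    else:
        if len(table):
            table["p_corrected"] = np.nan
        keep = table.get("n_voxels", pd.Series(dtype=int)) >= cfg.ancova_min_voxels
    labels = table.attrs.get("labels")
    table = table[keep].reset_index(drop=True)
    table.attrs["labels"] = labels
    extras = {"f_map": f3, "supra": supra, "null_max_sizes": null_sizes}
    return table, extras


def posthoc_pairwise(maps: np.ndarray, groups, pair: tuple[str, str],
                     covariates: np.ndarray, ancova_mask: np.ndarray,
                     affine: np.ndarray, voxel_size_mm: float,
                     cfg: InferenceConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Covariate-adjusted two-sample t within the ANCOVA mask.

    TFCE enhancement, two-sided max-|TFCE| FWE correction at
    ``posthoc_alpha`` and the ``posthoc_min_voxels`` extent rule.  Positive
    t means the second group of ``pair`` exceeds the first.
    """
    rng = rng or np.random.default_rng()
    ancova_mask = np.asarray(ancova_mask, dtype=bool)
    if not ancova_mask.any():
        raise ValueError("empty ANCOVA mask")
    g = pd.Series(np.asarray(groups))
    sel = g.isin(pair).to_numpy()
    if (g[sel] == pair[0]).sum() < 2 or (g[sel] == pair[1]).sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    Y = np.asarray(maps, dtype=float)[sel][:, ancova_mask]
    gsel = g[sel]
    N = Y.shape[0]
    ones = np.ones((N, 1))
    C = np.asarray(covariates, dtype=float)[sel]
    C = C - C.mean(axis=0)
    X_red = _prune_collinear(np.hstack([ones, C]))
    indicator = (gsel == pair[1]).to_numpy(float)[:, None]

    def tstat(Yv: np.ndarray) -> np.ndarray:
        X = np.hstack([X_red, indicator])
        pinv = np.linalg.pinv(X)
        beta = pinv @ Yv
        resid = Yv - X @ beta
        df = N - np.linalg.matrix_rank(X)
        sigma2 = (resid ** 2).sum(axis=0) / df
        var_b = (pinv @ pinv.T)[-1, -1]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta[-1] / np.sqrt(sigma2 * var_b)
        return np.where(sigma2 > 1e-300, t, 0.0)

    t_obs = tstat(Y)
    t3 = np.zeros(ancova_mask.shape)
    t3[ancova_mask] = t_obs
    tfce_obs = tfce_transform(t3, cfg.tfce)

    H_red = X_red @ np.linalg.pinv(X_red)
    fitted = H_red @ Y
    resid = Y - fitted
    exceed = np.zeros(ancova_mask.shape)
    for _ in range(cfg.n_perm):
        perm = rng.permutation(N)
        tp = tstat(fitted + resid[perm])
        t3p = np.zeros(ancova_mask.shape)
        t3p[ancova_mask] = tp
        null_max = np.abs(tfce_transform(t3p, cfg.tfce)).max()
        exceed += null_max >= np.abs(tfce_obs)
    p_fwe = (1.0 + exceed) / (cfg.n_perm + 1.0)

    supra = ancova_mask & (p_fwe < cfg.posthoc_alpha) & (np.abs(tfce_obs) > 0)
    table = _cluster_table(supra, t3, affine, voxel_size_mm,
                           cfg.tfce.connectivity)
    labels = table.attrs.get("labels")
    table = table[table["n_voxels"] >= cfg.posthoc_min_voxels].reset_index(drop=True)
    table.attrs["labels"] = labels
    extras = {"t_map": t3, "tfce_map": tfce_obs, "p_fwe": p_fwe, "supra": supra}
    return table, extras


# -------------------------------------------------- demographic statistics

def chisq_contingency(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on a count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_from_summary(n: np.ndarray, mean: np.ndarray, sd: np.ndarray
                       ) -> tuple[float, int, int]:
    """One-way ANOVA F from per-group (n, mean, sd) summary rows."""
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    k = len(n)
    if k < 2 or np.any(n < 2):
        raise ValueError("need >= 2 groups with n_i >= 2")
    grand = (n * mean).sum() / n.sum()
    ssb = (n * (mean - grand) ** 2).sum()
    ssw = ((n - 1) * sd ** 2).sum()
    df1, df2 = k - 1, int(n.sum()) - k
    if ssw == 0:
        if ssb == 0:
            raise ValueError("zero within- and between-group variance")
        return float("inf"), df1, df2
    return float((ssb / df1) / (ssw / df2)), df1, df2
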