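"""Cognitive composites and brain-behaviour correlation.

Domain composites (EM, EF, IPS, VF) are means of per-test z-scores against a
reference population (HC by default).  Mean DFC variability is extracted
from surviving clusters and related to the composites with covariate-
adjusted (partial) correlations, Bonferroni-corrected over the tested
(cluster x domain) family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def composite_z(raw: pd.DataFrame, domain_map: dict[str, list[str]],
                reference: pd.DataFrame | None = None,
                reference_index=None) -> pd.DataFrame:
    """Per-domain composite z-scores from raw test scores.

    Parameters
    ----------
    raw:
        One row per subject, one column per test.
    domain_map:
        Domain -> list of its test columns.
    reference:
        Optional frame of reference mean/sd per test (rows ``mean``/``sd``).
        If absent, statistics are computed over ``reference_index`` rows of
        ``raw`` (default: all rows).
    """
    if reference is None:
        ref_rows = raw if reference_index is None else raw.loc[reference_index]
        reference = pd.DataFrame({c: [ref_rows[c].mean(), ref_rows[c].std(ddof=1)]
                                  for c in raw.columns}, index=["mean", "sd"])
    out = {}
    for domain, tests in domain_map.items():
        zs = []
        for t in tests:
            sd = float(reference.loc["sd", t])
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"zero reference sd for test {t!r}")
            zs.append((raw[t] - float(reference.loc["mean", t])) / sd)
        out[domain] = pd.concat(zs, axis=1).mean(axis=1)
    return pd.DataFrame(out, index=raw.index)


def extract_cluster_means(maps: np.ndarray, cluster_masks: dict[str, np.ndarray]
                          ) -> pd.DataFrame:
    """Unweighted mean of each subject's map over each cluster's voxels.

    ``maps`` is ``(N, X, Y, Z)``; returns a frame with one column per
    cluster id.
    """
    if not cluster_masks:
        raise ValueError("no clusters to extract")
    maps = np.asarray(maps, dtype=float)
    return pd.DataFrame({
        cid: maps[:, np.asarray(m, dtype=bool)].mean(axis=1)
        for cid, m in cluster_masks.items()
    })


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None
                        ) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Returns ``(r, p)`` with a two-sided t-test on ``n - k - 2`` degrees of
    freedom (k covariates).  With no covariates this is the plain Pearson
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError("too few observations for the covariate count")
    X = np.column_stack([np.ones(n), C])
    hat = X @ np.linalg.pinv(X)
    rx = x - hat @ x
    ry = y - hat @ y
    sx, sy = np.sqrt((rx ** 2).sum()), np.sqrt((ry ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("degenerate residual variance")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def behavior_correlations(extracts: pd.DataFrame, composites: pd.DataFrame,
                          covariates: np.ndarray,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Partial correlation of every (cluster, domain) pair, Bonferroni-corrected.

    The Bonferroni family is the full cluster x domain grid.
    """
    rows = []
    m = extracts.shape[1] * composites.shape[1]
    for cid in extracts.columns:
        for dom in composites.columns:
            r, p = partial_correlation(extracts[cid].to_numpy(),
                                       composites[dom].to_numpy(), covariates)
            rows.append({"cluster": cid, "domain": dom, "r": r, "p": p,
                         "p_bonferroni": min(1.0, p * m),
                         "significant": p * m < alpha})
    return pd.DataFrame(rows)
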