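"""Seed-based static functional connectivity and network-template definition.

Each of the four networks (aDMN, pDMN, SN, ECN) is defined by a 10-mm
spherical seed at a fixed MNI centre.  Static FC is the voxel-wise Pearson
correlation of every voxel with the seed-mean time series, Fisher
z-transformed.  Group templates are the voxels with significantly positive
mean z in the reference (HC) group, assessed by a one-sample t-test with
sign-flip permutations, TFCE enhancement and max-statistic FWE correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tripledfc.core import BoldImage
from tripledfc.synth import SeedSpec, _sphere_mask
from tripledfc.tfce import TFCEParams, tfce_transform

#: Correlations are clipped at this bound before atanh so seed self-
#: correlation voxels stay finite.
R_CLIP = 1.0 - 1e-7


def make_seed_mask(seed: SeedSpec, grid_shape: tuple[int, int, int],
                   affine: np.ndarray) -> np.ndarray:
    """Voxels whose centre lies within the seed radius of the MNI centre."""
    mask = _sphere_mask(seed.center_mm, seed.radius_mm, tuple(grid_shape), affine)
    if not mask.any():
        raise ValueError(f"seed {seed.name!r} produces an empty mask on this grid")
    return mask


def seed_timeseries(img: BoldImage, mask: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty seed mask")
    return img.data[mask].mean(axis=0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilising z = atanh(r), with |r| clipped below 1."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _correlate_with(seed_ts: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``Y`` (T, V) with ``seed_ts`` (T,)."""
    s = seed_ts - seed_ts.mean()
    s_norm = np.sqrt((s ** 2).sum())
    if s_norm == 0:
        raise ValueError("seed time series has zero variance")
    Yc = Y - Y.mean(axis=0)
    norms = np.sqrt((Yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc.T @ s) / (norms * s_norm)
    return np.where(norms > 0, r, 0.0)


def static_fc_zmap(img: BoldImage, seed_ts: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Voxel-wise Fisher-z map of correlation with the seed series.

    Zero-variance voxels get z = 0.  Returns a 3D map (zero outside mask).
    """
    if img.n_volumes < 3:
        raise ValueError("need at least 3 time points")
    m = img.mask if mask is None else np.asarray(mask, dtype=bool)
    Y = img.data[m].T
    z = fisher_z(_correlate_with(np.asarray(seed_ts, dtype=float), Y))
    out = np.zeros(img.data.shape[:3])
    out[m] = z
    return out


@dataclass
class NetworkTemplate:
    """Binary network mask with inference provenance."""

    network: str
    mask: np.ndarray
    n_subjects: int
    n_permutations: int
    alpha: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def is_empty(self) -> bool:
        """True when no voxel survives (e.g. no positive connectivity)."""
        return not self.mask.any()


def one_sample_tmap(zstack: np.ndarray) -> np.ndarray:
    """Voxel-wise one-sample t statistic against zero over axis 0."""
    n = zstack.shape[0]
    mean = zstack.mean(axis=0)
    sd = zstack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def one_sample_template(zmaps: np.ndarray, network: str = "",
                        brain_mask: np.ndarray | None = None,
                        n_perm: int = 1000, alpha: float = 0.05,
                        tfce_params: TFCEParams | None = None,
                        rng: np.random.Generator | None = None
                        ) -> NetworkTemplate:
    """Positive-connectivity template from per-subject z-maps.

    Parameters
    ----------
    zmaps:
        Stack of per-subject 3D Fisher-z maps, shape ``(N, X, Y, Z)``.
    n_perm:
        Random sign-flip permutations for the max-TFCE null (the observed
        labelling is included, so the smallest attainable p is
        ``1 / (n_perm + 1)``).

    Returns the binary mask of voxels with positive t and FWE-corrected
    p < ``alpha``.
    """
    zmaps = np.asarray(zmaps, dtype=float)
    if zmaps.ndim != 4:
        raise ValueError("zmaps must be (N, X, Y, Z)")
    n = zmaps.shape[0]
    if n < 8:
        raise ValueError("need at least 8 subject maps")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if not np.any(zmaps):
        raise ValueError("all-zero input maps")
    rng = rng or np.random.default_rng()
    params = tfce_params or TFCEParams()
    bm = (np.ones(zmaps.shape[1:], dtype=bool) if brain_mask is None
          else np.asarray(brain_mask, dtype=bool))

    t_obs = np.where(bm, one_sample_tmap(zmaps), 0.0)
    tfce_obs = tfce_transform(t_obs, params)

    exceed = np.zeros_like(tfce_obs)
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_perm = np.where(bm, one_sample_tmap(zmaps * signs[:, None, None, None]), 0.0)
        max_null = tfce_transform(t_perm, params).max()
        exceed += max_null >= tfce_obs
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)

    mask = bm & (t_obs > 0) & (p_fwe < alpha)
    return NetworkTemplate(network, mask, n, n_perm, alpha)


def build_templates(images: list[BoldImage], seeds: list[SeedSpec],
                    gm_mask: np.ndarray | None = None,
                    n_perm: int = 1000, alpha: float = 0.05,
                    rng: np.random.Generator | None = None
                    ) -> dict[str, NetworkTemplate]:
    """Template per network from a reference-group image list."""
    out = {}
    for seed in seeds:
        zs = []
        for img in images:
            smask = make_seed_mask(seed, img.data.shape[:3], img.affine)
            ts = seed_timeseries(img, smask)
            zs.append(static_fc_zmap(img, ts, gm_mask))
        out[seed.network] = one_sample_template(
            np.stack(zs), seed.network, gm_mask, n_perm, alpha, rng=rng)
    return out
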