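"""Sliding-window dynamic functional connectivity and its temporal variability.

The windowed connectivity of a voxel with a network seed is the Pearson
correlation over a rectangular (untapered) window of ``width`` TRs, slid in
steps of ``step`` TRs, Fisher r-to-z transformed.  DFC variability is the
sample standard deviation of the windowed z values across windows — at the
study conditions (230 retained volumes, width 40, step 2) that is 96 windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tripledfc.core import BoldImage
from tripledfc.networks import R_CLIP, make_seed_mask, seed_timeseries
from tripledfc.synth import SeedSpec


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window bookkeeping: half-open windows ``[start, start+width)``."""

    width: int
    step: int
    n_windows: int
    starts: tuple[int, ...]

    @property
    def last_end(self) -> int:
        return self.starts[-1] + self.width


def make_windows(n_timepoints: int, width: int = 40, step: int = 2) -> WindowScheme:
    """Enumerate window start indices; K = floor((T - width)/step) + 1."""
    if width < 2:
        raise ValueError("window width must be at least 2")
    if step < 1:
        raise ValueError("step must be at least 1")
    if n_timepoints < width:
        raise ValueError(f"series of {n_timepoints} points shorter than window {width}")
    k = (n_timepoints - width) // step + 1
    starts = tuple(range(0, k * step, step))
    return WindowScheme(width, step, k, starts)


def _windowed_r_matrix(seed_ts: np.ndarray, Y: np.ndarray,
                       scheme: WindowScheme) -> np.ndarray:
    """Windowed Pearson r of every column of ``Y`` (T, V) with the seed.

    Uses prefix sums so cost is O(T V) independent of window count.
    Zero-variance windows yield r = 0.
    """
    s = np.asarray(seed_ts, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if s.shape[0] != Y.shape[0]:
        raise ValueError("seed and voxel series lengths differ")
    if s.shape[0] < scheme.last_end:
        raise ValueError("series shorter than the last window end")
    w = scheme.width
    a = np.asarray(scheme.starts)
    b = a + w

    def win_sum(cs):  # cs has a leading zero row
        return cs[b] - cs[a]

    cs_s = np.concatenate([[0.0], np.cumsum(s)])
    cs_s2 = np.concatenate([[0.0], np.cumsum(s ** 2)])
    zrow = np.zeros((1, Y.shape[1]))
    cs_y = np.vstack([zrow, np.cumsum(Y, axis=0)])
    cs_y2 = np.vstack([zrow, np.cumsum(Y ** 2, axis=0)])
    cs_sy = np.vstack([zrow, np.cumsum(Y * s[:, None], axis=0)])

    sum_s, sum_s2 = win_sum(cs_s), win_sum(cs_s2)
    sum_y, sum_y2, sum_sy = win_sum(cs_y), win_sum(cs_y2), win_sum(cs_sy)

    cov = w * sum_sy - sum_s[:, None] * sum_y
    var_s = w * sum_s2 - sum_s ** 2
    var_y = w * sum_y2 - sum_y ** 2
    var_s = np.clip(var_s, 0.0, None)
    var_y = np.clip(var_y, 0.0, None)
    denom = np.sqrt(var_s[:, None] * var_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    return np.where(denom > 1e-12 * w, r, 0.0)


def windowed_z_series(seed_ts: np.ndarray, voxel_ts: np.ndarray,
                      scheme: WindowScheme) -> np.ndarray:
    """Fisher-z windowed correlation series of length K for one voxel."""
    r = _windowed_r_matrix(seed_ts, np.asarray(voxel_ts, dtype=float), scheme)[:, 0]
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def variability(z_series: np.ndarray) -> float:
    """Sample standard deviation (denominator K-1) of the windowed z values."""
    z = np.asarray(z_series, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    return float(z.std(ddof=1))


def variability_map(img: BoldImage, seed: SeedSpec, scheme: WindowScheme,
                    mask: np.ndarray | None = None,
                    standardize: bool = False) -> np.ndarray:
    """Per-voxel DFC variability map for one seed (zero outside mask).

    Maps are raw standard deviations by default; ``standardize`` z-scores
    the map across in-mask voxels (some toolboxes do this before group
    statistics).
    """
    m = img.mask if mask is None else np.asarray(mask, dtype=bool)
    smask = make_seed_mask(seed, img.data.shape[:3], img.affine)
    s = seed_timeseries(img, smask)
    Y = img.data[m].T
    r = _windowed_r_matrix(s, Y, scheme)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    sd = z.std(axis=0, ddof=1)
    if standardize:
        spread = sd.std(ddof=1)
        sd = (sd - sd.mean()) / (spread if spread > 0 else 1.0)
    out = np.zeros(img.data.shape[:3])
    out[m] = sd
    return out
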