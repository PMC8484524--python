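"""Minimal volumetric preprocessing for already-normalised BOLD data.

Covers the post-normalisation steps of a standard resting-state pipeline:
initial volume discard, motion-based subject exclusion, Friston-24 +
tissue-signal nuisance regression, linear detrend, ideal (FFT) band-pass
filtering at 0.01-0.08 Hz, and 6-mm FWHM Gaussian smoothing.  The fixed
stage order is discard -> detrend -> nuisance regression -> band-pass ->
smooth; every temporal operator is linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from tripledfc.core import BoldImage

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def discard_initial_volumes(img: BoldImage, n: int) -> BoldImage:
    """Drop the first ``n`` volumes (dummy scans); metadata unchanged."""
    if n < 0 or n >= img.n_volumes:
        raise ValueError(f"cannot discard {n} of {img.n_volumes} volumes")
    return img.with_data(img.data[..., n:])


def exclude_by_motion(motion: np.ndarray, trans_limit_mm: float = 3.0,
                      rot_limit_deg: float = 3.0) -> bool:
    """Subject-exclusion rule: cumulative translation > limit on any axis, or
    cumulative rotation > limit.

    "Cumulative" is displacement relative to the first retained volume.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] == 0:
        raise ValueError("motion trace must be a non-empty (T, 6) array")
    disp = motion - motion[0]
    max_trans = np.max(np.abs(disp[:, :3]))
    max_rot = np.max(np.abs(disp[:, 3:]))
    return bool(max_trans > trans_limit_mm or max_rot > rot_limit_deg)


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston autoregressive expansion of the 6 rigid parameters.

    Columns are ``[p(t), p(t-1), p(t)^2, p(t-1)^2]`` for each parameter
    (24 total); the lagged terms are zero at the first volume.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion trace must be (T >= 2, 6)")
    lagged = np.vstack([np.zeros(6), motion[:-1]])
    return np.hstack([motion, lagged, motion ** 2, lagged ** 2])


def tissue_mean_regressors(img: BoldImage, masks: dict[str, np.ndarray]
                           ) -> np.ndarray:
    """Global / WM / CSF mean time series as nuisance columns (T, 3).

    The global mean is taken over the brain mask; masked-out voxels never
    contribute.
    """
    cols = [img.data[img.mask].mean(axis=0)]
    for name in ("WM", "CSF"):
        m = masks[name] & img.mask if name in masks else None
        if m is None or not m.any():
            cols.append(np.zeros(img.n_volumes))
        else:
            cols.append(img.data[m].mean(axis=0))
    return np.column_stack(cols)


def regress_nuisance(ts: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualise time series against nuisance regressors (+ intercept).

    ``ts`` is ``(T,)`` or ``(T, V)``.  Collinear columns are dropped with a
    warning rather than failing.
    """
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y = ts[:, None] if one_d else ts
    X = np.column_stack([np.ones(len(Y)), np.asarray(nuisance, dtype=float)])
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} collinear nuisance column(s)")
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid[:, 0] if one_d else resid


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the best-fit line; the output is orthogonal to [1, t]."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 samples to detrend")
    t = np.arange(ts.shape[0], dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    return ts - X @ beta


def bandpass(ts: np.ndarray, tr: float, low: float = 0.01,
             high: float = 0.08) -> np.ndarray:
    """Ideal rectangular frequency-domain band-pass after linear detrend.

    Passband amplitudes are preserved exactly; everything outside
    ``[low, high]`` (including DC) is zeroed.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[0]
    if n < 3:
        raise ValueError("series too short to filter")
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyquist = 0.5 / tr
    if not (0 <= low < high <= nyquist + 1e-12):
        raise ValueError(f"band ({low}, {high}) invalid for Nyquist {nyquist}")
    x = detrend_linear(ts)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(x, axis=0)
    keep = (freqs >= low) & (freqs <= high)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n, axis=0)


def smooth_gaussian(img: BoldImage, fwhm_mm: float = 6.0) -> BoldImage:
    """Per-volume 3D Gaussian smoothing with the given FWHM in millimetres."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return img
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / img.voxel_size_mm
    out = ndimage.gaussian_filter(img.data, sigma=(sigma_vox,) * 3 + (0.0,))
    return img.with_data(out)


@dataclass
class PreprocParams:
    """Parameters of the standard pipeline (defaults as used in the study)."""

    n_discard: int = 10
    trans_limit_mm: float = 3.0
    rot_limit_deg: float = 3.0
    band: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 6.0
    use_global: bool = True


def preprocess_subject(img: BoldImage, motion: np.ndarray,
                       tissue: dict[str, np.ndarray] | None = None,
                       params: PreprocParams | None = None
                       ) -> BoldImage | None:
    """Run the full per-subject pipeline; ``None`` if excluded by motion.

    Order: discard -> detrend -> nuisance regression (Friston-24 + tissue
    means) -> ideal band-pass -> spatial smoothing.
    """
    p = params or PreprocParams()
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != img.n_volumes:
        raise ValueError("motion rows must equal BOLD volume count")
    img = discard_initial_volumes(img, p.n_discard)
    motion = motion[p.n_discard:]
    if exclude_by_motion(motion, p.trans_limit_mm, p.rot_limit_deg):
        return None

    Y = img.voxel_timeseries()              # (T, V) in-mask
    Y = detrend_linear(Y)
    nuis = [friston24(motion)]
    if tissue is not None:
        tcols = tissue_mean_regressors(img, tissue)
        if not p.use_global:
            tcols = tcols[:, 1:]
        nuis.append(detrend_linear(tcols))
    Y = regress_nuisance(Y, np.hstack(nuis))
    Y = bandpass(Y, img.tr, *p.band)

    out = np.zeros_like(img.data)
    out[img.mask] = Y.T
    return smooth_gaussian(img.with_data(out), p.fwhm_mm)
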