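"""Threshold-free cluster enhancement (TFCE).

TFCE(v) = sum over thresholds h (from dh to the map maximum in steps dh) of
e(v, h)^E * h^H * dh, where e(v, h) is the voxel extent of the connected
component containing v in the supra-threshold set {map >= h}.  Defaults
H = 2, E = 0.5, dh = max/100, 26-connectivity.  Negative values are enhanced
by transforming the negated map and negating the result, so the output is a
signed map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class TFCEParams:
    H: float = 2.0
    E: float = 0.5
    dh: float | None = None  # None -> map max / n_steps
    n_steps: int = 100
    connectivity: int = 26   # 6, 18 or 26 neighbours in 3D

    def __post_init__(self) -> None:
        if self.H <= 0 or self.E <= 0:
            raise ValueError("H and E must be positive")


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim != 3:
        return np.ones((3,) * ndim, dtype=bool)
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def _tfce_one_sided(pos: np.ndarray, params: TFCEParams) -> np.ndarray:
    vmax = float(pos.max(initial=0.0))
    out = np.zeros_like(pos, dtype=float)
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    struct = _structure(pos.ndim, params.connectivity)
    heights = np.arange(dh, vmax + dh * 0.5, dh)
    for h in heights:
        labels, n = ndimage.label(pos >= h, structure=struct)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += (sizes[labels] ** params.E) * (h ** params.H) * dh
    return out


def tfce_transform(stat_map: np.ndarray, params: TFCEParams | None = None
                   ) -> np.ndarray:
    """Signed TFCE enhancement of a statistic map of any dimensionality."""
    params = params or TFCEParams()
    m = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("statistic map contains non-finite values")
    pos = _tfce_one_sided(np.clip(m, 0.0, None), params)
    neg = _tfce_one_sided(np.clip(-m, 0.0, None), params)
    return pos - neg
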