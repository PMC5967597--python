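"""Fixed-threshold VoI segmentation and fixed-bin-number gray-level quantization.

The segmentation rule sets a per-study threshold from the subsample of the
lower 15% of uptake values inside the crude input VoI (taken to contain
background and healthy-tissue activity only): threshold = mean(S) + 3 sd(S).
Voxels strictly above the threshold are kept, restricted to the largest
26-connected component to drop satellite background speckle.

Quantization maps in-mask SUV onto Q gray levels (default Q = 32) with the
fixed-bin-number rule  level = floor((Q-1) (Y - min) / (max - min)) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import UptakeVolume, VoIMask

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def segmentation_threshold(values: np.ndarray, subsample_frac: float = 0.15,
                           k_sd: float = 3.0, ddof: int = 1) -> float:
    """Threshold = mean + k_sd * sd of the lowest ``subsample_frac`` of values.

    The cut point is the linear-interpolation quantile of the input values;
    ties at the cut point are included on the low side.  ``ddof=1`` uses the
    sample (n-1) standard-deviation convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 voxels to estimate a threshold")
    cut = np.quantile(v, subsample_frac)
    sub = v[v <= cut]
    if sub.size < 2:
        raise ValueError("lower subsample has fewer than 2 voxels")
    sd = float(np.std(sub, ddof=ddof)) if sub.size > ddof else 0.0
    return float(np.mean(sub)) + k_sd * sd


def largest_connected_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a boolean volume."""
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n == 0:
        raise ValueError("mask has no foreground voxels")
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def threshold_segment(vol: UptakeVolume, crude_mask: VoIMask, *,
                      subsample_frac: float = 0.15, k_sd: float = 3.0,
                      sd_ddof: int = 1) -> VoIMask:
    """Segment the tumor inside a crude VoI by the fixed-threshold rule.

    Returns the largest 26-connected component of in-VoI voxels with uptake
    strictly above mean(S) + k_sd * sd(S), S being the lower
    ``subsample_frac`` of in-VoI values.  Raises ``ValueError`` when no voxel
    exceeds the threshold.
    """
    if vol.shape != crude_mask.shape:
        raise ValueError("volume and crude mask shapes differ")
    inside = crude_mask.values
    y = vol.values[inside]
    t = segmentation_threshold(y, subsample_frac, k_sd, ddof=sd_ddof)
    above = inside & (vol.values > t)
    if not above.any():
        raise ValueError(f"no voxel exceeds segmentation threshold {t:.4g}")
    keep = largest_connected_component(above)
    return VoIMask(keep, vol.spacing_mm, vol.origin_mm)


@dataclass
class QuantizedVolume:
    """Integer gray-level volume with levels in 1..Q inside the mask.

    Out-of-mask voxels carry level 0.  ``vmin``/``vmax`` record the source
    SUV range within the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    q: int
    vmin: float
    vmax: float

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def quantize(vol: UptakeVolume, mask: VoIMask, q: int = 32) -> QuantizedVolume:
    """Requantize in-mask uptake into ``q`` gray levels by fixed bin number.

    level = floor((q-1)(Y - min) / (max - min)) + 1, over in-mask voxels
    only; the max-value voxel attains level q.  Raises ``ValueError`` when
    the in-mask values are constant.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    m = mask.values
    y = vol.values[m]
    vmin, vmax = float(y.min()), float(y.max())
    if vmax <= vmin:
        raise ValueError("in-mask uptake is constant; quantization undefined")
    lv = np.floor((q - 1) * (y - vmin) / (vmax - vmin)).astype(int) + 1
    lv = np.clip(lv, 1, q)  # guard float round-up at Y == max
    levels = np.zeros(vol.shape, dtype=int)
    levels[m] = lv
    return QuantizedVolume(levels, m.copy(), int(q), vmin, vmax)
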