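"""Radiomic texture, histogram and morphology features of a segmented VoI.

Feature definitions follow the Image Biomarker Standardisation Initiative
(IBSI) conventions: intensity moments on raw SUV, entropy/uniformity and
histogram gradients on the Q-level quantized histogram, GLCM features
averaged over the 13 sign-collapsed unit-displacement directions of the
3-D grid, GLSZM non-uniformity features over 26-connected equal-level
zones, and PCA-based morphological ellipsoid descriptors.

Feature names carry the frame suffix used downstream (``entropy.GLCM``,
``CoV.HIST``, ``Intensity.GLSZM``, ``PCA.major``, ...).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from skimage.measure import marching_cubes, mesh_surface_area

from .segmentation import CONNECTIVITY_26, QuantizedVolume
from .volume_io import UptakeVolume, VoIMask

__all__ = [
    "glcm_directions", "cooccurrence_matrix", "histogram_features",
    "glcm_features", "glszm_features", "size_zone_matrix",
    "morphology_features", "avidity_features", "texture_feature_names",
]


def glcm_directions() -> list[tuple[int, int, int]]:
    """The 13 unique 3-D adjacency directions (26-connectivity modulo sign).

    Offsets with the first nonzero component positive; distance 1 in grid
    units on each axis.
    """
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                off = (dx, dy, dz)
                if off == (0, 0, 0):
                    continue
                first = next(v for v in off if v != 0)
                if first > 0:
                    dirs.append(off)
    return dirs


# ---------------------------------------------------------------------------
# Histogram (first-order) features


def histogram_features(y_in_mask: np.ndarray, quantized: QuantizedVolume) -> dict[str, float]:
    """Twelve first-order features.

    Moments (mean, median, variance, skewness, kurtosis, CoV) are computed
    on raw SUV; entropy, uniformity and the histogram-gradient features on
    the Q-level quantized histogram.  The histogram gradient is the
    difference of successive bin counts, attributed to the upper gray level;
    skewness/kurtosis are NaN for constant input.
    """
    y = np.asarray(y_in_mask, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty mask")
    mean = float(np.mean(y))
    var = float(np.var(y))
    sd = np.sqrt(var)
    feats = {
        "mean.HIST": mean,
        "median.HIST": float(np.median(y)),
        "variance.HIST": var,
        "skewness.HIST": float(stats.skew(y)) if var > 0 else float("nan"),
        "kurtosis.HIST": float(stats.kurtosis(y)) if var > 0 else float("nan"),
        "CoV.HIST": sd / mean if mean != 0 else 0.0 if var == 0 else float("nan"),
    }
    if var == 0:
        feats["CoV.HIST"] = 0.0

    q = quantized.q
    levels = quantized.in_mask_levels()
    counts = np.bincount(levels, minlength=q + 1)[1:].astype(float)
    p = counts / counts.sum()
    nz = p > 0
    feats["entropy.HIST"] = float(-(p[nz] * np.log2(p[nz])).sum())
    feats["uniformity.HIST"] = float((p * p).sum())

    d = np.diff(counts)  # gradient at gray level i+2 ... attributed to upper level
    imax, imin = int(np.argmax(d)), int(np.argmin(d))
    feats["max.gradient.HIST"] = float(d[imax])
    feats["max.gradient.gray.HIST"] = float(imax + 2)
    feats["min.gradient.HIST"] = float(d[imin])
    feats["min.gradient.gray.HIST"] = float(imin + 2)
    return feats


# ---------------------------------------------------------------------------
# GLCM


def cooccurrence_matrix(quantized: QuantizedVolume, direction: tuple[int, int, int],
                        normalize: bool = True) -> np.ndarray:
    """Symmetric Q x Q co-occurrence matrix for one displacement direction.

    Counts in-mask voxel pairs separated by ``direction``; each pair is
    accumulated in both (i, j) and (j, i).  Normalized to sum 1 by default.
    """
    lv = quantized.levels
    m = quantized.mask
    q = quantized.q
    sl_a, sl_b = [], []
    for off in direction:
        if off >= 0:
            sl_a.append(slice(None, lv.shape[len(sl_a)] - off if off else None))
            sl_b.append(slice(off, None))
        else:
            sl_a.append(slice(-off, None))
            sl_b.append(slice(None, off))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = m[sl_a] & m[sl_b]
    i = lv[sl_a][valid] - 1
    j = lv[sl_b][valid] - 1
    mat = np.bincount(i * q + j, minlength=q * q).astype(float).reshape(q, q)
    mat = mat + mat.T
    if normalize:
        tot = mat.sum()
        if tot == 0:
            raise ValueError("no in-mask voxel pairs in this direction")
        mat /= tot
    return mat


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    q = p.shape[0]
    i = np.arange(1, q + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    adiff = np.abs(ii - jj)
    nz = p > 0
    mu = float((p * ii).sum())             # marginal mean (symmetric P)
    var = float((p * (ii - mu) ** 2).sum())
    corr = 1.0 if var == 0 else float(((p * (ii - mu) * (jj - mu)).sum()) / var)
    return {
        "entropy.GLCM": float(-(p[nz] * np.log2(p[nz])).sum()),
        "dissimilarity.GLCM": float((p * adiff).sum()),
        "homogeneity.GLCM": float((p / (1.0 + adiff)).sum()),
        "contrast.GLCM": float((p * adiff**2).sum()),
        "autocorrelation.GLCM": float((p * ii * jj).sum()),
        "max.probability.GLCM": float(p.max()),
        "correlation.GLCM": corr,
        "uniformity.GLCM": float((p * p).sum()),
    }


def glcm_features(quantized: QuantizedVolume, directions=None) -> dict[str, float]:
    """Eight GLCM features averaged over the 13 volume directions.

    Each direction's symmetric co-occurrence matrix is normalized to sum 1
    before feature evaluation; feature values are then averaged across
    directions (directions with no valid pair are skipped).
    """
    if directions is None:
        directions = glcm_directions()
    acc: dict[str, list[float]] = {}
    n_used = 0
    for d in directions:
        try:
            p = cooccurrence_matrix(quantized, d, normalize=True)
        except ValueError:
            continue
        n_used += 1
        for k, v in _glcm_features_single(p).items():
            acc.setdefault(k, []).append(v)
    if n_used == 0:
        raise ValueError("no direction yielded an in-mask voxel pair")
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM


def size_zone_matrix(quantized: QuantizedVolume) -> dict[tuple[int, int], int]:
    """Counts of 26-connected equal-level zones keyed by (gray level, size)."""
    mat: dict[tuple[int, int], int] = {}
    lv = quantized.levels
    for g in range(1, quantized.q + 1):
        labels, n = ndimage.label((lv == g) & quantized.mask, structure=CONNECTIVITY_26)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            mat[(g, int(s))] = mat.get((g, int(s)), 0) + 1
    return mat


def glszm_features(quantized: QuantizedVolume) -> dict[str, float]:
    """Zone-size and gray-level non-uniformity of the size-zone matrix.

    ``Size.zone.GLSZM`` = sum_s (sum_g M_gs)^2 / N_zones (zone-size
    non-uniformity); ``Intensity.GLSZM`` = sum_g (sum_s M_gs)^2 / N_zones
    (gray-level non-uniformity).
    """
    mat = size_zone_matrix(quantized)
    if not mat:
        raise ValueError("empty mask: no zones")
    n_zones = sum(mat.values())
    by_size: dict[int, int] = {}
    by_gray: dict[int, int] = {}
    for (g, s), c in mat.items():
        by_size[s] = by_size.get(s, 0) + c
        by_gray[g] = by_gray.get(g, 0) + c
    szv = sum(v * v for v in by_size.values()) / n_zones
    inv = sum(v * v for v in by_gray.values()) / n_zones
    return {"Size.zone.GLSZM": float(szv), "Intensity.GLSZM": float(inv)}


# ---------------------------------------------------------------------------
# Morphology


def morphology_features(mask: VoIMask, spacing_mm=None) -> dict[str, float]:
    """Asphericity and PCA-based ellipsoid descriptors of the binary mask.

    Volume V = voxel count x voxel volume; surface S from a marching-cubes
    mesh at the 0.5 iso-level of the zero-padded mask indicator, lightly
    mollified with a 0.7-voxel Gaussian to suppress the staircase surface
    bias of a binary isosurface, world-scaled;
    asphericity = S / (36 pi V^2)^(1/3) - 1.  The lambda are eigenvalues of
    the (population) covariance of in-mask voxel centers; axis length
    k = 4 sqrt(lambda_k); elongation = sqrt(lambda_minor / lambda_major),
    flatness = sqrt(lambda_least / lambda_major).
    """
    m = mask.values
    spacing = np.asarray(mask.spacing_mm if spacing_mm is None else spacing_mm, dtype=float)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty mask")
    vox_vol = float(np.prod(spacing))
    volume_mm3 = n * vox_vol

    idx = np.argwhere(m).astype(float) * spacing
    cov = np.cov(idx.T, ddof=0) if n > 1 else np.zeros((3, 3))
    lam = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]  # major >= minor >= least
    if lam[-1] <= 0:
        raise ValueError("degenerate mask: voxel centers are coplanar")

    padded = ndimage.gaussian_filter(np.pad(m, 3).astype(float), 0.7)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    surface_mm2 = float(mesh_surface_area(verts, faces))
    asphericity = surface_mm2 / (36.0 * np.pi * volume_mm3**2) ** (1.0 / 3.0) - 1.0

    return {
        "volume_ml": volume_mm3 / 1000.0,
        "surface_cm2": surface_mm2 / 100.0,
        "asphericity": float(asphericity),
        "PCA.major": float(4.0 * np.sqrt(lam[0])),
        "PCA.minor": float(4.0 * np.sqrt(lam[1])),
        "PCA.least": float(4.0 * np.sqrt(lam[2])),
        "PCA.elongation": float(np.sqrt(lam[1] / lam[0])),
        "PCA.flatness": float(np.sqrt(lam[2] / lam[0])),
    }


# ---------------------------------------------------------------------------
# Avidity


def avidity_features(vol: UptakeVolume, mask: VoIMask) -> dict[str, float]:
    """SUVmax, SUVmean, segmented volume (ml) and TLG = SUVmean x volume."""
    y = vol.values[mask.values]
    if y.size == 0:
        raise ValueError("empty mask")
    volume_ml = mask.count() * vol.voxel_volume_mm3 / 1000.0
    suv_mean = float(np.mean(y))
    return {
        "SUVmax": float(np.max(y)),
        "SUVmean": suv_mean,
        "volume_ml": volume_ml,
        "TLG": suv_mean * volume_ml,
    }


def texture_feature_names() -> list[str]:
    """The 28 textural-frame variable names, in canonical order."""
    return [
        "asphericity", "PCA.major", "PCA.minor", "PCA.least",
        "PCA.elongation", "PCA.flatness",
        "mean.HIST", "median.HIST", "variance.HIST", "skewness.HIST",
        "kurtosis.HIST", "CoV.HIST", "entropy.HIST", "uniformity.HIST",
        "min.gradient.HIST", "max.gradient.HIST",
        "min.gradient.gray.HIST", "max.gradient.gray.HIST",
        "entropy.GLCM", "dissimilarity.GLCM", "homogeneity.GLCM",
        "contrast.GLCM", "autocorrelation.GLCM", "max.probability.GLCM",
        "correlation.GLCM", "uniformity.GLCM",
        "Size.zone.GLSZM", "Intensity.GLSZM",
    ]
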