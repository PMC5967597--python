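"""Volume and mask I/O, SUV scaling, VoI cropping, feature-table serialization.

Conventions
-----------
All geometry is metric: a voxel at index ``(i, j, k)`` has world-coordinate
center ``origin + index * spacing`` (mm).  Indices are 0-based and only used
internally; every exported coordinate is in world mm, because voxel spacing
is generally anisotropic in PET.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class UptakeVolume:
    """A 3-D scalar SUV grid with voxel spacing and world origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Nonnegative, finite uptake values in SUV units.
    spacing_mm : ndarray, shape (3,)
        Strictly positive voxel spacing along each axis (mm).
    origin_mm : ndarray, shape (3,)
        World coordinate of the center of voxel (0, 0, 0) (mm).
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.values.ndim}-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be nonnegative")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def voxel_centers_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centers, optionally mask-restricted.

        Returns an (n, 3) array in C index order (or mask order when a mask
        is given).
        """
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(np.asarray(mask, dtype=bool))
        return self.origin_mm + idx * self.spacing_mm


@dataclass
class VoIMask:
    """Binary volume-of-interest mask sharing the geometry of its volume."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.values.any():
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = origin_mm
    return aff


def write_volume(vol: UptakeVolume, path) -> None:
    """Write an :class:`UptakeVolume` as a NIfTI-1 file (float64 data)."""
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.spacing_mm, vol.origin_mm))
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def read_volume(path) -> UptakeVolume:
    """Read a 3-D scalar NIfTI volume.

    Raises ``ValueError`` for non-3-D images or missing voxel dimensions.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D scalar volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("NIfTI header has nonpositive voxel spacing")
    origin = np.asarray(img.affine)[:3, 3]
    return UptakeVolume(np.asarray(data, dtype=float), np.asarray(zooms, dtype=float), origin)


def write_mask(mask: VoIMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm))
    img.header.set_zooms(tuple(mask.spacing_mm))
    nib.save(img, str(path))


def read_mask(path) -> VoIMask:
    vol = read_volume(path)
    return VoIMask(vol.values > 0.5, vol.spacing_mm, vol.origin_mm)


def suv_scale(counts_volume: UptakeVolume, activity_conc_kbq_per_cc: np.ndarray | None = None,
              injected_dose_kbq: float = None, body_weight_g: float = None) -> UptakeVolume:
    """Scale an activity-concentration volume into SUV.

    SUV = concentration (kBq/cc) / (injected dose (kBq) / body weight (g)),
    i.e. uptake relative to the whole-body mean concentration.

    ``activity_conc_kbq_per_cc`` defaults to the values already stored in
    ``counts_volume`` (assumed calibrated to kBq/cc).
    """
    if injected_dose_kbq is None or injected_dose_kbq <= 0:
        raise ValueError("injected dose must be > 0 kBq")
    if body_weight_g is None or body_weight_g <= 0:
        raise ValueError("body weight must be > 0 g")
    conc = counts_volume.values if activity_conc_kbq_per_cc is None else np.asarray(activity_conc_kbq_per_cc, dtype=float)
    suv = conc / (injected_dose_kbq / body_weight_g)
    return UptakeVolume(suv, counts_volume.spacing_mm, counts_volume.origin_mm)


# ---------------------------------------------------------------------------
# Volumes of interest


@dataclass
class BoxVoI:
    """Axis-aligned box VoI given by opposite corners in world mm."""

    min_mm: np.ndarray
    max_mm: np.ndarray

    def __post_init__(self):
        self.min_mm = np.asarray(self.min_mm, dtype=float).reshape(3)
        self.max_mm = np.asarray(self.max_mm, dtype=float).reshape(3)
        if np.any(self.max_mm < self.min_mm):
            raise ValueError("box max must be >= box min on every axis")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_mm, dtype=float)
        return np.all((p >= self.min_mm) & (p <= self.max_mm), axis=-1)


@dataclass
class EllipsoidVoI:
    """Axis-aligned ellipsoid VoI: center and semi-axes in world mm."""

    center_mm: np.ndarray
    semi_axes_mm: np.ndarray

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        self.semi_axes_mm = np.asarray(self.semi_axes_mm, dtype=float).reshape(3)
        if np.any(self.semi_axes_mm <= 0):
            raise ValueError("semi-axes must be strictly positive")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        p = (np.asarray(points_mm, dtype=float) - self.center_mm) / self.semi_axes_mm
        return np.sum(p * p, axis=-1) <= 1.0


def voi_from_json(path_or_dict) -> BoxVoI | EllipsoidVoI:
    """Load a VoI from a JSON config.

    Recognized forms: ``{"center_mm": [...], "semi_axes_mm": [...]}`` for an
    ellipsoid or ``{"box_min_mm": [...], "box_max_mm": [...]}`` for a box.
    """
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = json.load(fh)
    if "center_mm" in cfg:
        return EllipsoidVoI(cfg["center_mm"], cfg["semi_axes_mm"])
    if "box_min_mm" in cfg:
        return BoxVoI(cfg["box_min_mm"], cfg["box_max_mm"])
    raise ValueError("VoI config must define center_mm/semi_axes_mm or box_min_mm/box_max_mm")


def crop_to_voi(vol: UptakeVolume, voi) -> tuple[UptakeVolume, VoIMask]:
    """Crop a volume to the bounding box of a crude input VoI.

    The mask marks voxels whose *centers* lie inside the VoI; the cropped
    grid covers the mask's index bounding box.  Raises ``ValueError`` when
    the VoI does not intersect the grid.
    """
    idx = np.indices(vol.shape).reshape(3, -1).T
    centers = vol.origin_mm + idx * vol.spacing_mm
    inside = voi.contains(centers).reshape(vol.shape)
    if not inside.any():
        raise ValueError("VoI does not contain any voxel center of the grid")
    lo, hi = [], []
    for ax in range(3):
        proj = np.any(inside, axis=tuple(a for a in range(3) if a != ax))
        nz = np.nonzero(proj)[0]
        lo.append(nz[0])
        hi.append(nz[-1] + 1)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    new_origin = vol.origin_mm + np.array(lo) * vol.spacing_mm
    cropped = UptakeVolume(vol.values[sl], vol.spacing_mm, new_origin)
    mask = VoIMask(inside[sl], vol.spacing_mm, new_origin)
    return cropped, mask


# ---------------------------------------------------------------------------
# Feature tables

FRAME_ROW_LABEL = "__frame__"


def write_feature_table(table: pd.DataFrame, frames: dict[str, str], path) -> None:
    """Write a study x variable table as CSV with a frame-label row.

    The second line of the file labels each variable with its feature frame
    (clinical | structural | textural), keeping downstream analysis
    tool-agnostic.
    """
    frame_row = pd.DataFrame([{c: frames.get(c, "") for c in table.columns}], index=[FRAME_ROW_LABEL])
    out = pd.concat([frame_row, table.astype(object)])
    out.to_csv(path, index_label="study_id")


def read_feature_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    raw = pd.read_csv(path, index_col="study_id")
    if FRAME_ROW_LABEL not in raw.index:
        raise ValueError("feature table is missing its frame-label row")
    frames = {c: str(v) for c, v in raw.loc[FRAME_ROW_LABEL].items()}
    table = raw.drop(index=FRAME_ROW_LABEL)
    for c in table.columns:
        try:
            table[c] = pd.to_numeric(table[c])
        except (ValueError, TypeError):
            pass
    return table, frames
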