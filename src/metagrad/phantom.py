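"""Synthetic 3-D tumor phantoms with known ellipsoidal ground truth.

A phantom is built from an ellipsoidal radial coordinate
``u(x) = (x - mu)' Sigma^{-1} (x - mu)`` (squared Mahalanobis radius) and a
radial uptake profile: either monotonically decreasing (an active,
homogeneous core) or unimodal (a low-activity necrotic core surrounded by
an avid rim).  The profile is evaluated on the voxel grid, a constant
background is added, the image is blurred with an isotropic Gaussian
point-spread function specified in mm FWHM, i.i.d. Gaussian noise is added,
and the result is clipped at zero so SUV stays nonnegative.

The geometry is fully deterministic from the spec; the seed governs the
noise only, so two phantoms sharing a spec and seed are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import UptakeVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

PROFILE_KINDS = ("monotone_decreasing", "unimodal_necrotic_core")


@dataclass
class ProfileParams:
    """Radial profile parameters (all in SUV / dimensionless u units).

    peak_suv : profile maximum above background.
    core_suv : central (u = 0) value for the necrotic-core kind.
    mode_radius : u at which the necrotic-core profile peaks.
    decay_scale : exponential decay scale in u beyond the peak.
    """

    peak_suv: float
    core_suv: float = 0.0
    mode_radius: float = 0.0
    decay_scale: float = 1.0

    def validate(self, kind: str) -> None:
        for name in ("peak_suv", "core_suv", "mode_radius", "decay_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"profile parameter {name} must be nonnegative")
        if self.decay_scale == 0:
            raise ValueError("decay_scale must be > 0")
        if kind == "unimodal_necrotic_core":
            if self.mode_radius <= 0:
                raise ValueError("unimodal profile requires mode_radius > 0")
            if self.core_suv > self.peak_suv:
                raise ValueError("core_suv must not exceed peak_suv")


def make_profile_function(kind: str, params: ProfileParams) -> Callable[[np.ndarray], np.ndarray]:
    """Return the radial uptake profile f(u) for a phantom kind.

    ``monotone_decreasing``: f(u) = peak * exp(-u / decay), nonincreasing.
    ``unimodal_necrotic_core``: linear ramp from core_suv at u = 0 to
    peak_suv at u = mode_radius, then exponential decay — nondecreasing up
    to the mode, nonincreasing after.
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {kind!r}; expected one of {PROFILE_KINDS}")
    params.validate(kind)
    peak, core = params.peak_suv, params.core_suv
    mode, decay = params.mode_radius, params.decay_scale

    if kind == "monotone_decreasing":
        def f(u):
            u = np.asarray(u, dtype=float)
            return peak * np.exp(-u / decay)
    else:
        def f(u):
            u = np.asarray(u, dtype=float)
            rising = core + (peak - core) * np.clip(u / mode, 0.0, 1.0)
            falling = peak * np.exp(-np.clip(u - mode, 0.0, None) / decay)
            return np.where(u <= mode, rising, falling)

    return f


@dataclass
class PhantomSpec:
    """Full description of a synthetic tumor study.

    ``sigma_true`` is the SPD shape matrix (mm^2) whose u = 1 surface is the
    reference tumor ellipsoid; it must lie inside the grid.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (4.30, 4.30, 4.25)
    mu_true: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sigma_true: np.ndarray = field(default_factory=lambda: np.eye(3) * 400.0)
    profile_kind: str = "monotone_decreasing"
    profile_params: ProfileParams = field(default_factory=lambda: ProfileParams(peak_suv=10.0, decay_scale=0.8))
    background_suv: float = 1.0
    psf_fwhm_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.mu_true = np.asarray(self.mu_true, dtype=float).reshape(3)
        self.sigma_true = np.asarray(self.sigma_true, dtype=float)
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be positive")
        if not np.allclose(self.sigma_true, self.sigma_true.T):
            raise ValueError("sigma_true must be symmetric")
        if np.linalg.eigvalsh(self.sigma_true).min() <= 0:
            raise ValueError("sigma_true must be positive definite")
        if self.profile_kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.profile_kind!r}")
        self.profile_params.validate(self.profile_kind)
        if self.profile_params.peak_suv <= self.background_suv:
            raise ValueError("profile peak must exceed background SUV")
        if self.background_suv < 0 or self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("background_suv, psf_fwhm_mm and noise_sd must be nonnegative")
        self._check_containment()

    def _check_containment(self):
        # bounding half-width of the u=1 ellipsoid along grid axis k is sqrt(Sigma_kk)
        half = np.sqrt(np.diag(self.sigma_true))
        spacing = np.asarray(self.voxel_spacing_mm, dtype=float)
        extent_lo = np.zeros(3)
        extent_hi = (np.asarray(self.grid_shape) - 1) * spacing
        if np.any(self.mu_true - half < extent_lo) or np.any(self.mu_true + half > extent_hi):
            raise ValueError("u=1 ellipsoid of (mu_true, sigma_true) is not contained in the grid")

    def profile_function(self) -> Callable[[np.ndarray], np.ndarray]:
        return make_profile_function(self.profile_kind, self.profile_params)


@dataclass
class GroundTruth:
    """Sidecar record of a phantom's generating parameters."""

    mu_true: np.ndarray
    sigma_true: np.ndarray
    profile_kind: str
    profile_params: ProfileParams
    background_suv: float
    seed: int
    profile: Callable[[np.ndarray], np.ndarray]

    def to_json(self, path) -> None:
        rec = {
            "mu_mm": list(map(float, self.mu_true)),
            "sigma_mm2_row_major": [float(v) for v in np.asarray(self.sigma_true).ravel()],
            "profile_kind": self.profile_kind,
            "profile_params": {
                "peak_suv": self.profile_params.peak_suv,
                "core_suv": self.profile_params.core_suv,
                "mode_radius": self.profile_params.mode_radius,
                "decay_scale": self.profile_params.decay_scale,
            },
            "background_suv": self.background_suv,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=2)


def true_radii(spec: PhantomSpec, points_mm: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis radius of world points under the true ellipsoid."""
    d = np.asarray(points_mm, dtype=float) - spec.mu_true
    sol = np.linalg.solve(spec.sigma_true, d.T)
    return np.einsum("ij,ji->i", d, sol)


def generate_phantom(spec: PhantomSpec) -> tuple[UptakeVolume, GroundTruth]:
    """Generate a synthetic SUV volume and its ground-truth record.

    Voxel SUV = background + profile(u_true), Gaussian-blurred at the stated
    FWHM (in world mm, converted per-axis to voxel sigmas), plus i.i.d.
    zero-mean Gaussian noise of sd ``noise_sd``, clipped at 0.
    """
    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    centers = idx * spacing  # origin at 0
    u = true_radii(spec, centers)
    f = spec.profile_function()
    values = spec.background_suv + f(u)
    values = values.reshape(spec.grid_shape)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spacing
        values = gaussian_filter(values, sigma=sigma_vox, mode="nearest")

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    values = np.clip(values, 0.0, None)
    vol = UptakeVolume(values, spacing, np.zeros(3))
    truth = GroundTruth(spec.mu_true.copy(), spec.sigma_true.copy(), spec.profile_kind,
                        spec.profile_params, spec.background_suv, spec.seed, f)
    return vol, truth


def rotation_matrix(angles_deg: tuple[float, float, float]) -> np.ndarray:
    """Rotation composed of rotations about the z, y and x grid axes."""
    az, ay, ax = np.deg2rad(angles_deg)
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


def default_phantom_spec(kind: str = "monotone_decreasing", *, seed: int = 0,
                         noise_sd: float = 0.2, psf_fwhm_mm: float = 10.0) -> PhantomSpec:
    """Study conditions used throughout the test phantoms.

    A 64^3 grid at PET-like anisotropic spacing; a rotated triaxial tumor
    with semi-axes 30/24/18 mm, background SUV 1, peak SUV 10 above
    background; 10-mm reconstruction blur and additive noise emulating a
    filtered-backprojection image.
    """
    shape = (64, 64, 64)
    spacing = (4.30, 4.30, 4.25)
    center = (np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
    mu = center + np.array([3.1, -2.4, 1.7])
    rot = rotation_matrix((25.0, 15.0, 40.0))
    sigma = rot @ np.diag([30.0**2, 24.0**2, 18.0**2]) @ rot.T
    if kind == "monotone_decreasing":
        params = ProfileParams(peak_suv=10.0, decay_scale=0.8)
    else:
        params = ProfileParams(peak_suv=10.0, core_suv=2.5, mode_radius=0.6, decay_scale=0.8)
    return PhantomSpec(grid_shape=shape, voxel_spacing_mm=spacing, mu_true=mu,
                       sigma_true=sigma, profile_kind=kind, profile_params=params,
                       background_suv=1.0, psf_fwhm_mm=psf_fwhm_mm, noise_sd=noise_sd,
                       seed=seed)
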