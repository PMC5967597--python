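"""Shared fixtures: phantom studies and their structural fits.

The heavy ellipsoidal fits are session-scoped so unit tests and the
acceptance suite share one computation per study condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from metagrad.phantom import (PhantomSpec, ProfileParams, default_phantom_spec,
                              generate_phantom, rotation_matrix)
from metagrad.pipeline import RunConfig, StudyInput, default_crude_voi, run_extract
from metagrad.segmentation import threshold_segment
from metagrad.structural import EllipsoidalUptakeModel, EllipsoidalUptakeResults
from metagrad.volume_io import crop_to_voi

MODERATE_NOISE_SD = 1.0   # 0.1 x peak SUV
HIGH_NOISE_SD = 3.0       # 0.3 x peak SUV


@dataclass
class FittedPhantom:
    spec: PhantomSpec
    truth: object
    results: EllipsoidalUptakeResults
    n_segmented: int

    def mu_error_mm(self) -> float:
        return float(np.linalg.norm(self.results.ellipsoid.mu - self.truth.mu_true))

    def principal_axis_error_deg(self) -> float:
        w, v = np.linalg.eigh(self.truth.sigma_true)
        ax_true = v[:, -1]
        ax_est = self.results.ellipsoid.principal_axis()
        c = min(abs(float(ax_true @ ax_est)), 1.0)
        return float(np.degrees(np.arccos(c)))


def fit_phantom(spec: PhantomSpec, fit_seed: int = 0) -> FittedPhantom:
    vol, truth = generate_phantom(spec)
    cvol, crude = crop_to_voi(vol, default_crude_voi(spec))
    seg = threshold_segment(cvol, crude)
    res = EllipsoidalUptakeModel.from_volume(cvol, seg).fit(seed=fit_seed)
    return FittedPhantom(spec, truth, res, seg.count())


def small_phantom_spec(kind: str = "monotone_decreasing", *, seed: int = 0,
                       noise_sd: float = 0.2, psf_fwhm_mm: float = 10.0) -> PhantomSpec:
    """A 32^3 phantom for cheap unit tests (not a study condition)."""
    shape = (32, 32, 32)
    spacing = (4.30, 4.30, 4.25)
    center = (np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
    rot = rotation_matrix((25.0, 15.0, 40.0))
    sigma = rot @ np.diag([24.0**2, 19.0**2, 15.0**2]) @ rot.T
    if kind == "monotone_decreasing":
        params = ProfileParams(peak_suv=10.0, decay_scale=0.8)
    else:
        params = ProfileParams(peak_suv=10.0, core_suv=2.5, mode_radius=0.6, decay_scale=0.8)
    return PhantomSpec(grid_shape=shape, voxel_spacing_mm=spacing,
                       mu_true=center + np.array([2.0, -1.5, 1.0]), sigma_true=sigma,
                       profile_kind=kind, profile_params=params, background_suv=1.0,
                       psf_fwhm_mm=psf_fwhm_mm, noise_sd=noise_sd, seed=seed)


@pytest.fixture(scope="session")
def noiseless_monotone_fit() -> FittedPhantom:
    """Noiseless, unblurred monotone phantom: uptake is an exact function of u."""
    spec = default_phantom_spec("monotone_decreasing", seed=1, noise_sd=0.0, psf_fwhm_mm=0.0)
    return fit_phantom(spec, fit_seed=1)


@pytest.fixture(scope="session")
def necrotic_fit() -> FittedPhantom:
    """Noiseless necrotic-core phantom: unimodal radial profile."""
    spec = default_phantom_spec("unimodal_necrotic_core", seed=2, noise_sd=0.0, psf_fwhm_mm=0.0)
    return fit_phantom(spec, fit_seed=2)


@pytest.fixture(scope="session")
def replicate_fits() -> list[FittedPhantom]:
    """20 moderate-noise monotone replicates (parameter-recovery batch)."""
    return [fit_phantom(default_phantom_spec("monotone_decreasing", seed=s,
                                             noise_sd=MODERATE_NOISE_SD), fit_seed=s)
            for s in range(20)]


@pytest.fixture(scope="session")
def noise_ladder_h0(replicate_fits) -> dict[float, list[float]]:
    """H0 per study at noise sd {0, 1, 3} SUV, 10 seeds each.

    The sd=1 level reuses the first ten parameter-recovery replicates.
    """
    out: dict[float, list[float]] = {MODERATE_NOISE_SD: [f.results.h0 for f in replicate_fits[:10]]}
    for sd in (0.0, HIGH_NOISE_SD):
        out[sd] = [fit_phantom(default_phantom_spec("monotone_decreasing", seed=s,
                                                    noise_sd=sd), fit_seed=s).results.h0
                   for s in range(10)]
    return out


@pytest.fixture(scope="session")
def extraction_batch(tmp_path_factory):
    """Full pipeline run on three default phantoms, with outputs on disk."""
    out_dir = tmp_path_factory.mktemp("extract")
    config = RunConfig(seed=11, out_dir=str(out_dir))
    kinds = ["monotone_decreasing", "unimodal_necrotic_core"]
    studies = [StudyInput(study_id=f"phantom{i:02d}",
                          phantom=default_phantom_spec(kinds[i % 2], seed=20 + i))
               for i in range(3)]
    table = run_extract(studies, config)
    return table, out_dir
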