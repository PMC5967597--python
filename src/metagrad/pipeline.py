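"""End-to-end extraction pipeline: volume -> segmentation -> structural fit
-> radiomics -> feature-table row.

A run is fully determined by its :class:`RunConfig` plus per-study inputs;
all randomness (phantom noise, optimizer restarts) flows from the config's
root seed, and the config (with a content hash) is persisted alongside the
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import radiomics as rx
from .feature_space import FeatureTable, assemble_features
from .phantom import PhantomSpec, generate_phantom
from .segmentation import quantize, threshold_segment
from .structural import EllipsoidalUptakeModel, FitConfig
from .volume_io import (EllipsoidVoI, UptakeVolume, crop_to_voi, read_volume,
                        voi_from_json, write_feature_table)

log = logging.getLogger("metagrad")

DEFAULT_CLINICAL = {"grade": "intermediate", "subtype": "STS", "age": 50.0, "sex": "M"}


@dataclass
class RunConfig:
    """Pipeline constants; serializable, persisted next to outputs."""

    q_levels: int = 32
    seg_subsample_frac: float = 0.15
    seg_k_sd: float = 3.0
    seg_sd_ddof: int = 1
    voi_margin: float = 1.4     # crude VoI semi-axes / true semi-axes, phantoms
    n_starts: int = 2
    max_modes: int = 200
    min_voxels: int = 30
    var_ddof: int = 1
    quantile_method: str = "linear"
    seed: int = 0
    out_dir: str | None = None

    def fit_config(self) -> FitConfig:
        return FitConfig(min_voxels=self.min_voxels, n_starts=self.n_starts,
                         max_modes=self.max_modes, var_ddof=self.var_ddof,
                         quantile_method=self.quantile_method)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyInput:
    """One study: either an image path + VoI, or a phantom spec."""

    study_id: str
    image: str | UptakeVolume | None = None
    voi: object | None = None          # BoxVoI / EllipsoidVoI / path to JSON
    phantom: PhantomSpec | None = None
    clinical: dict = field(default_factory=dict)

    def load(self, config: RunConfig):
        if self.phantom is not None:
            vol, _ = generate_phantom(self.phantom)
            voi = self.voi or default_crude_voi(self.phantom, margin=config.voi_margin)
            return vol, voi
        if self.image is None:
            raise FileNotFoundError(f"study {self.study_id}: no image given")
        vol = self.image if isinstance(self.image, UptakeVolume) else None
        if vol is None:
            p = Path(self.image)
            if not p.exists():
                raise FileNotFoundError(f"study {self.study_id}: missing image {p}")
            vol = read_volume(p)
        if self.voi is None:
            raise ValueError(f"study {self.study_id}: a VoI is required for image input")
        voi = self.voi if hasattr(self.voi, "contains") else voi_from_json(self.voi)
        return vol, voi


def default_crude_voi(spec: PhantomSpec, margin: float = 1.4) -> EllipsoidVoI:
    """Crude axis-aligned ellipsoidal VoI drawn around a phantom tumor."""
    semi = margin * np.sqrt(np.diag(spec.sigma_true))
    return EllipsoidVoI(center_mm=spec.mu_true, semi_axes_mm=semi)


@dataclass
class StudyRecord:
    study_id: str
    structural: dict[str, float]
    radiomic: dict[str, float]
    clinical: dict
    profile: pd.DataFrame
    summary: dict


def extract_study(vol: UptakeVolume, crude_voi, config: RunConfig,
                  clinical: dict | None = None, study_id: str = "study",
                  fit_seed: int = 0) -> StudyRecord:
    """Run segmentation, structural fit and radiomics on one study."""
    t0 = time.perf_counter()
    cvol, crude_mask = crop_to_voi(vol, crude_voi)
    seg = threshold_segment(cvol, crude_mask, subsample_frac=config.seg_subsample_frac,
                            k_sd=config.seg_k_sd, sd_ddof=config.seg_sd_ddof)
    quant = quantize(cvol, seg, q=config.q_levels)
    log.info("study %s: segmented %d voxels (%.2fs)", study_id, seg.count(),
             time.perf_counter() - t0)

    t1 = time.perf_counter()
    model = EllipsoidalUptakeModel.from_volume(cvol, seg, config=config.fit_config())
    res = model.fit(seed=fit_seed)
    log.info("study %s: structural fit RSS=%.4g H0=%.4g (%.2fs)", study_id,
             res.rss, res.h0, time.perf_counter() - t1)

    structural = res.structural_summary().to_dict()

    y = cvol.values[seg.values]
    hist = rx.histogram_features(y, quant)
    glcm = rx.glcm_features(quant)
    glszm = rx.glszm_features(quant)
    morph = rx.morphology_features(seg)
    avidity = rx.avidity_features(cvol, seg)
    radiomic = {**hist, **glcm, **glszm,
                **{k: v for k, v in morph.items() if k.startswith(("PCA.", "asphericity"))}}

    clin = dict(DEFAULT_CLINICAL)
    clin.update({"SUVmax": avidity["SUVmax"], "SUVmean": avidity["SUVmean"],
                 "TLG": avidity["TLG"], "volume": avidity["volume_ml"]})
    clin.update(clinical or {})

    summary = {
        "study_id": study_id,
        "n_voxels": int(seg.count()),
        "mu_mm": [float(v) for v in res.ellipsoid.mu],
        "sigma_mm2_row_major": [float(v) for v in res.ellipsoid.sigma.ravel()],
        "H0": res.h0, "H1": res.h1,
        "rss": res.rss,
        "mode_u": res.profile.mode_u(),
        "gradient_quantiles": structural,
        "volume_ml": avidity["volume_ml"],
        "surface_cm2": morph["surface_cm2"],
    }
    return StudyRecord(study_id, structural, radiomic, clin, res.profile_frame(), summary)


def run_extract(studies: list[StudyInput], config: RunConfig) -> FeatureTable:
    """Extract the 44-variable feature row for each study.

    Deterministic given config and study inputs; when ``config.out_dir`` is
    set, writes features.csv, per-study profile CSVs and summary JSONs, and
    the config (with content hash).
    """
    file_handler = None
    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        file_handler = logging.FileHandler(Path(config.out_dir) / "run.log")
        file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(file_handler)
        log.setLevel(logging.INFO)
    records = []
    for i, study in enumerate(studies):
        try:
            vol, voi = study.load(config)
            rec = extract_study(vol, voi, config, clinical=study.clinical,
                                study_id=study.study_id,
                                fit_seed=(config.seed + 1009 * i) % (2**31))
        except Exception as e:
            if file_handler is not None:
                log.removeHandler(file_handler)
                file_handler.close()
            raise type(e)(f"study {study.study_id}: {e}") from e
        records.append(rec)
    if file_handler is not None:
        log.removeHandler(file_handler)
        file_handler.close()

    table = assemble_features({r.study_id: r.structural for r in records},
                              {r.study_id: r.radiomic for r in records},
                              {r.study_id: r.clinical for r in records})
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(table.data, table.frames, out / "features.csv")
        for r in records:
            r.profile.to_csv(out / f"{r.study_id}_profile.csv", index_label="voxel")
            with open(out / f"{r.study_id}_summary.json", "w") as fh:
                json.dump(r.summary, fh, indent=2)
        meta = {"config": config.to_dict(), "config_hash": config.content_hash()}
        with open(out / "run_config.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return table
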