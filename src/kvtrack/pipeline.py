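"""End-to-end pipeline: phantom -> training set -> cGAN -> tracking -> metrics.

Two test-set modes mirror the two ways ground truth can be constructed
for clinical kV images:

* ``masked``    — markers are embedded in the CT, projected, harmonically
  inpainted out of the kV-like images, and Poisson noise is added; the
  ground truth is the marker-free contour projection.
* ``markerless`` — clean projections are rigidly shifted in 2D according
  to a known 3D couch shift via the cone-beam projective mapping; the
  ground truth is the identically shifted contour projection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augmentation import MASK_PATH_EPS_MM, build_training_set
from .cgan import NetworkConfig, TrainConfig, train_patient_model
from .evaluation import per_angle_stats, summarize
from .phantom import PhantomSpec, default_spec, embed_markers, generate_phantom
from .preprocessing import add_poisson_noise, inpaint_regions, marker_footprint_2d, shift_image
from .projection import BeamGeometry, ProjectionImage, desk_geometry, forward_project, project_shift
from .tracking import SegMask2D, TrackingRecord, track_arc
from .volumes import write_volume

logger = logging.getLogger("kvtrack")

__all__ = ["RunConfig", "run_pipeline", "load_geometry", "save_geometry", "records_to_frame"]


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    out_root: str
    seed: int = 0
    phantom: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    augmentation: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    test: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        return cfg

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def load_geometry(path: str | Path) -> BeamGeometry:
    d = yaml.safe_load(Path(path).read_text())
    if "detector_shape" in d:
        d["detector_shape"] = tuple(d["detector_shape"])
    return BeamGeometry(**d)


def save_geometry(geom: BeamGeometry, path: str | Path) -> None:
    d = {
        "SAD": geom.SAD,
        "SID": geom.SID,
        "detector_shape": list(geom.detector_shape),
        "detector_pitch": geom.detector_pitch,
    }
    Path(path).write_text(yaml.safe_dump(d))


def records_to_frame(records: list[TrackingRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "angle": r.angle,
                "pred_u_px": r.pred_centroid_px[0] if r.pred_centroid_px else np.nan,
                "pred_v_px": r.pred_centroid_px[1] if r.pred_centroid_px else np.nan,
                "gt_u_px": r.gt_centroid_px[0] if r.gt_centroid_px else np.nan,
                "gt_v_px": r.gt_centroid_px[1] if r.gt_centroid_px else np.nan,
                "error_aplat_mm": r.error_aplat_mm,
                "error_si_mm": r.error_si_mm,
                "dsc": r.dsc,
                "msd_mm": r.msd_mm,
                "empty_prediction": r.empty_prediction,
                "multi_region": r.multi_region,
            }
        )
    return pd.DataFrame(rows)


def build_test_set(
    ct, contour, markers, geom: BeamGeometry, cfg: dict, seed: int
) -> tuple[list[ProjectionImage], list[SegMask2D]]:
    """Construct (kv_images, ground-truth masks) for one of the two modes."""
    mode = cfg.get("mode", "markerless")
    angle_step = float(cfg.get("angle_step", 45.0))
    photons = int(cfg.get("photons_at_max", 10_000))
    rng = np.random.default_rng(seed)
    n = int(round(360.0 / angle_step))
    angles = [i * angle_step + float(cfg.get("angle_offset", 0.0)) for i in range(n)]
    kv_images, gt_masks = [], []
    if mode == "markerless":
        shift3d = np.asarray(cfg.get("couch_shift", (3.0, -2.0, 1.5)), dtype=float)
        for ang in angles:
            kv = forward_project(ct, geom, ang)
            mask = forward_project(contour, geom, ang, kind="mask")
            s2d = project_shift(shift3d, ang, geom)
            kv = shift_image(kv, s2d)
            mask = shift_image(mask, s2d)
            kv = add_poisson_noise(kv, photons, rng)
            kv.kind = "kv"
            kv_images.append(kv)
            gt_masks.append(SegMask2D(mask.values > MASK_PATH_EPS_MM, kv.pitch, ang))
    elif mode == "masked":
        if not markers:
            raise ValueError("masked test mode requires phantom markers")
        marker_mu = cfg.get("marker_attenuation", 0.30)
        radius = cfg.get("marker_radius", 0.6)
        ct_m = embed_markers(ct, markers, radius, marker_mu)
        for ang in angles:
            kv = forward_project(ct_m, geom, ang)
            foot = marker_footprint_2d(markers, geom, ang, radius)
            kv = inpaint_regions(kv, foot)
            kv = add_poisson_noise(kv, photons, rng)
            kv.kind = "kv"
            mask = forward_project(contour, geom, ang, kind="mask")
            kv_images.append(kv)
            gt_masks.append(SegMask2D(mask.values > MASK_PATH_EPS_MM, kv.pitch, ang))
    else:
        raise ValueError(f"unknown test mode '{mode}'")
    return kv_images, gt_masks


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the metrics summary as a dict.

    The artifact tree under ``cfg.out_root`` is self-describing: the
    resolved configuration and all seeds are written alongside the
    volumes, training manifest, model checkpoint, tracking records, and
    the final summary.
    """
    t0 = time.time()
    out = Path(cfg.out_root)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(cfg.resolved(), indent=2))

    spec = PhantomSpec(**cfg.phantom) if cfg.phantom else default_spec(with_markers=True)
    geom = (
        BeamGeometry(**{**cfg.geometry, "detector_shape": tuple(cfg.geometry["detector_shape"])})
        if cfg.geometry
        else desk_geometry(64)
    )
    logger.info("stage=phantom seed=%d grid=%s", cfg.seed, spec.grid_shape)
    ct, contour, markers = generate_phantom(spec, seed=cfg.seed)
    write_volume(ct, out / "ct.nii.gz")
    write_volume(contour, out / "prostate.nii.gz")
    (out / "markers.json").write_text(json.dumps([list(m) for m in markers]))

    aug = dict(cfg.augmentation)
    logger.info("stage=build_training_set %s", aug)
    manifest = build_training_set(
        ct,
        contour,
        geom,
        out / "trainset",
        n_augment=int(aug.get("n_augment", 4)),
        max_shift=float(aug.get("max_shift", 10.0)),
        max_rot=float(aug.get("max_rot", 10.0)),
        angle_step=float(aug.get("angle_step", 45.0)),
        seed=cfg.seed + 1,
    )

    ncfg = NetworkConfig(**{
        "image_size": geom.detector_shape[0],
        "base_channels": 8,
        "generator_depth": 3,
        **cfg.network,
    })
    tcfg = TrainConfig(**{"seed": cfg.seed + 2, **cfg.training})
    logger.info("stage=train epochs=%d pairs=%d", tcfg.epochs, manifest.n_pairs)
    artifact = train_patient_model(manifest, ncfg, tcfg)
    artifact.save(out / "model.npz")
    pd.DataFrame(artifact.history).to_csv(out / "training_curves.csv", index=False)

    logger.info("stage=test_set mode=%s", cfg.test.get("mode", "markerless"))
    kv_images, gt_masks = build_test_set(ct, contour, markers, geom, cfg.test, cfg.seed + 3)
    # kv images are normalised with the training-set scale before inference
    scale = manifest.intensity_max or 1.0
    kv_norm = [
        ProjectionImage(kv.values / scale, kv.pitch, kv.angle, "kv") for kv in kv_images
    ]
    threshold = float(cfg.test.get("threshold", 0.10))
    logger.info("stage=track n_images=%d threshold=%.2f", len(kv_norm), threshold)
    records = track_arc(artifact.generator, kv_norm, gt_masks, geom, threshold)
    records_to_frame(records).to_csv(out / "records.csv", index=False)

    logger.info("stage=evaluate")
    summary = summarize(records).to_dict()
    summary["runtime_s"] = time.time() - t0
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    per_angle_stats(records, bin_deg=float(cfg.test.get("angle_step", 45.0))).to_csv(
        out / "per_angle.csv", index=False
    )
    return summary
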