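"""Rigid-motion augmentation and paired training-set assembly.

Before treatment, the planning volumes are repeatedly perturbed by small
rigid transforms (translations up to 10 mm, rotations up to 10 degrees by
default, emulating setup error and whole-patient motion) and each perturbed
geometry is forward-projected over the full arc.  Every anatomy DRR is
paired with the prostate-contour projection of the *same* transformed
geometry at the same gantry angle; these pairs are the conditional-GAN
training units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import affine_transform

from .projection import BeamGeometry, ProjectionImage, forward_project
from .volumes import VoxelVolume

__all__ = [
    "RigidTransform",
    "PairedProjection",
    "TrainingManifest",
    "sample_transform",
    "apply_rigid_transform",
    "build_training_set",
]

# projected contour path lengths above this (mm) count as prostate in the
# binary target; suppresses trilinear interpolation fringe
MASK_PATH_EPS_MM = 0.1


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the isocentre (degrees, applied in x -> y -> z order)
    followed by a translation (mm)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix R = Rz @ Ry @ Rx (x applied first)."""
        ax, ay, az = np.deg2rad(self.rotation)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]], float)
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]], float)
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]], float)
        return rz @ ry @ rx

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in self.translation) and all(
            v == 0.0 for v in self.rotation
        )


@dataclass
class PairedProjection:
    """One cGAN training unit: anatomy DRR x and binary prostate target y."""

    x: ProjectionImage
    y: ProjectionImage
    angle: float
    transform_id: int

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError("paired projections must share shape")
        if not set(np.unique(self.y.values)) <= {0.0, 1.0}:
            raise ValueError("target projection must be binary")


def sample_transform(max_shift: float, max_rot: float, rng: np.random.Generator) -> RigidTransform:
    """Draw each translation component from U(-max_shift, max_shift) mm and
    each rotation component from U(-max_rot, max_rot) degrees, independently."""
    if max_shift < 0 or max_rot < 0:
        raise ValueError("augmentation limits must be >= 0")
    t = rng.uniform(-max_shift, max_shift, 3) if max_shift > 0 else np.zeros(3)
    r = rng.uniform(-max_rot, max_rot, 3) if max_rot > 0 else np.zeros(3)
    return RigidTransform(tuple(t), tuple(r))


def apply_rigid_transform(volume: VoxelVolume, t: RigidTransform) -> VoxelVolume:
    """Resample ``volume`` under the rigid map p -> R p + translation.

    Rotation is about the isocentre (world origin).  Trilinear
    interpolation, zero (air) fill outside the grid; grid metadata is
    unchanged.  The identity transform returns a bit-exact copy.
    """
    if t.is_identity:
        return volume.copy()
    R = t.matrix()
    S = np.diag(volume.spacing)
    Sinv = np.diag(1.0 / volume.spacing)
    # output voxel index -> input voxel index, via world coordinates:
    # p_in = R^T (p_out - translation)
    matrix = Sinv @ R.T @ S
    offset = Sinv @ (R.T @ (volume.origin - np.asarray(t.translation)) - volume.origin)
    vals = affine_transform(
        volume.values, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    return VoxelVolume(vals, volume.spacing.copy(), volume.origin.copy())


@dataclass
class TrainingManifest:
    """Index of a paired training set stored as per-transform NPZ shards.

    ``intensity_max`` is the maximum anatomy-DRR value over the whole set;
    network inputs are normalised to [0, 1] by this single set-wide scale
    so inter-angle intensity relationships are preserved.
    """

    geometry: dict
    angle_step: float
    n_augment: int
    max_shift: float
    max_rot: float
    seed: int
    intensity_max: float
    shards: list = field(default_factory=list)  # paths, one per transform
    transforms: list = field(default_factory=list)  # [{translation, rotation}, ...]
    n_pairs: int = 0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "TrainingManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)

    def iter_pairs(self):
        """Yield (x, y, angle, transform_id) lazily; x normalised to [0, 1]."""
        scale = self.intensity_max if self.intensity_max > 0 else 1.0
        for tid, shard in enumerate(self.shards):
            with np.load(shard) as z:
                xs, ys, angles = z["x"], z["y"], z["angles"]
            for i in range(xs.shape[0]):
                yield xs[i].astype(np.float64) / scale, ys[i].astype(np.float64), float(
                    angles[i]
                ), tid

    def load_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Materialise the whole set as (x, y, angles) arrays."""
        xs, ys, angles = [], [], []
        for x, y, a, _ in self.iter_pairs():
            xs.append(x)
            ys.append(y)
            angles.append(a)
        return np.stack(xs), np.stack(ys), np.asarray(angles)


def build_training_set(
    ct: VoxelVolume,
    contour: VoxelVolume,
    geom: BeamGeometry,
    out_dir: str | Path,
    n_augment: int = 100,
    max_shift: float = 10.0,
    max_rot: float = 10.0,
    angle_step: float = 1.0,
    seed: int = 0,
    ray_step: float | None = None,
) -> TrainingManifest:
    """Assemble the paired training set.

    For each of ``n_augment`` sampled rigid transforms, the *same* transform
    is applied to the CT and the contour, both are projected over the full
    arc, and the contour projection is binarised (projected path length
    > 0.1 mm).  Total pairs = ``n_augment * 360 / angle_step``; with the
    default 100 transforms at a 1-degree step that is 36,000 pairs.
    """
    if not ct.same_grid(contour):
        raise ValueError("CT and contour must share grid metadata")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_angles = int(round(360.0 / angle_step))
    angles = np.arange(n_angles) * angle_step

    shards, transforms = [], []
    intensity_max = 0.0
    n_pairs = 0
    for tid in range(n_augment):
        t = sample_transform(max_shift, max_rot, rng)
        # cropping to the nonzero support leaves line integrals unchanged
        # and keeps ray marching cheap, especially for the contour volume
        ct_t = apply_rigid_transform(ct, t).crop_to_support()
        contour_t = apply_rigid_transform(contour, t).crop_to_support()
        rows, cols = geom.detector_shape
        xs = np.empty((n_angles, rows, cols), dtype=np.float32)
        ys = np.empty((n_angles, rows, cols), dtype=np.uint8)
        for i, ang in enumerate(angles):
            px = forward_project(ct_t, geom, ang, step=ray_step)
            py = forward_project(contour_t, geom, ang, step=ray_step, kind="mask")
            xs[i] = px.values
            ys[i] = py.values > MASK_PATH_EPS_MM
        intensity_max = max(intensity_max, float(xs.max()))
        shard = out_dir / f"pairs_{tid:04d}.npz"
        np.savez(shard, x=xs, y=ys, angles=angles)
        shards.append(str(shard))
        transforms.append(
            {"translation": list(t.translation), "rotation": list(t.rotation)}
        )
        n_pairs += n_angles

    manifest = TrainingManifest(
        geometry={
            "SAD": geom.SAD,
            "SID": geom.SID,
            "detector_shape": list(geom.detector_shape),
            "detector_pitch": geom.detector_pitch,
        },
        angle_step=angle_step,
        n_augment=n_augment,
        max_shift=max_shift,
        max_rot=max_rot,
        seed=seed,
        intensity_max=intensity_max,
        shards=shards,
        transforms=transforms,
        n_pairs=n_pairs,
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
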