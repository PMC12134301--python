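"""Synthetic digital-pelvis phantom.

Generates a pelvis-like attenuation volume (soft-tissue body ellipsoid,
higher-attenuation bone structures, an ellipsoidal prostate) together with
the binary prostate contour volume and, optionally, implanted
high-attenuation fiducial markers.  Every downstream stage of the tracking
pipeline — forward projection, augmentation, network training, evaluation —
is exercised against this phantom, whose geometry is known exactly.

Attenuations are linear coefficients in arbitrary consistent mm^-1 units;
the projector only ever forms line integrals, so no Hounsfield calibration
is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import BinaryVolume, VoxelVolume

__all__ = ["PhantomSpec", "generate_phantom", "embed_markers", "default_spec"]


@dataclass
class PhantomSpec:
    """Geometric and radiological description of the digital pelvis.

    All lengths in mm, attenuations in mm^-1.  ``bone_descriptors`` is a
    list of ``(center, semiaxes, attenuation)`` ellipsoids added on top of
    the soft-tissue background (e.g. femoral heads, a sacrum block).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    prostate_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prostate_semiaxes: tuple[float, float, float] = (20.0, 15.0, 18.0)
    body_semiaxes: tuple[float, float, float] = (85.0, 90.0, 80.0)
    bone_descriptors: list = field(
        default_factory=lambda: [
            ((-60.0, 0.0, 0.0), (14.0, 30.0, 14.0), 0.045),
            ((60.0, 0.0, 0.0), (14.0, 30.0, 14.0), 0.045),
            ((0.0, 10.0, 55.0), (30.0, 22.0, 14.0), 0.040),
        ]
    )
    tissue_attenuations: dict = field(
        default_factory=lambda: {"soft": 0.020, "prostate": 0.026, "marker": 0.30}
    )
    marker_positions: list = field(default_factory=list)
    marker_radius: float = 0.6
    texture_sigma_frac: float = 0.02

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        pc = np.asarray(self.prostate_center, float)
        pa = np.asarray(self.prostate_semiaxes, float)
        ba = np.asarray(self.body_semiaxes, float)
        if np.any(pa <= 0) or np.any(ba <= 0):
            raise ValueError("semiaxes must be strictly positive")
        # prostate strictly inside body (body centred at isocentre): the
        # prostate's axis-aligned bounding box must fall inside the body
        # ellipsoid with margin.
        corners = pc[None, :] + pa[None, :] * _SIGNS
        if np.any(np.sum((corners / ba) ** 2, axis=1) >= 1.0):
            raise ValueError("prostate ellipsoid must lie strictly inside the body ellipsoid")
        atts = dict(self.tissue_attenuations)
        for k in ("soft", "prostate", "marker"):
            if k not in atts:
                raise ValueError(f"tissue_attenuations missing class '{k}'")
        if any(v < 0 for v in atts.values()):
            raise ValueError("attenuations must be >= 0")
        bone_atts = [b[2] for b in self.bone_descriptors]
        if bone_atts:
            if not (atts["marker"] > max(bone_atts)):
                raise ValueError("marker attenuation must exceed bone attenuation")
            if not (min(bone_atts) > atts["soft"]):
                raise ValueError("bone attenuation must exceed soft tissue attenuation")
        if atts["soft"] <= 0:
            raise ValueError("soft tissue attenuation must be > 0")
        for m in self.marker_positions:
            m = np.asarray(m, float)
            if np.sum(((m - pc) / pa) ** 2) >= 1.0:
                raise ValueError("markers must lie inside the prostate ellipsoid")
        if self.marker_radius <= 0:
            raise ValueError("marker_radius must be positive")


_SIGNS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
)


def _ellipsoid_mask(vol_axes, center, semiaxes) -> np.ndarray:
    x, y, z = vol_axes
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (
        ((x[:, None, None] - cx) / ax) ** 2
        + ((y[None, :, None] - cy) / ay) ** 2
        + ((z[None, None, :] - cz) / az) ** 2
    ) < 1.0


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[VoxelVolume, BinaryVolume, list[np.ndarray]]:
    """Build the attenuation volume, prostate contour, and marker list.

    The contour marks exactly the voxels whose centres fall inside the
    prostate ellipsoid.  Attenuation is additive per tissue class: body
    soft tissue, a prostate increment, and bone ellipsoids; mild seeded
    Gaussian texture (``texture_sigma_frac`` of the soft-tissue value,
    clipped at 0) is added inside the body so projections are not piecewise
    flat.  Markers are *not* burnt in here — use :func:`embed_markers`.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    ct = VoxelVolume(np.zeros(shape), np.asarray(spec.voxel_spacing, float))
    axes = ct.voxel_centres()
    atts = spec.tissue_attenuations

    body = _ellipsoid_mask(axes, (0.0, 0.0, 0.0), spec.body_semiaxes)
    values = np.where(body, atts["soft"], 0.0)
    for center, semiaxes, mu in spec.bone_descriptors:
        bone = _ellipsoid_mask(axes, center, semiaxes)
        values[bone] = mu
    prost = _ellipsoid_mask(axes, spec.prostate_center, spec.prostate_semiaxes)
    values[prost] = atts["prostate"]
    if spec.texture_sigma_frac > 0:
        noise = rng.normal(0.0, spec.texture_sigma_frac * atts["soft"], size=shape)
        values = np.where(body, np.clip(values + noise, 0.0, None), values)
    ct.values = values

    contour = BinaryVolume(prost.astype(float), ct.spacing.copy(), ct.origin.copy())
    markers = [np.asarray(m, dtype=float) for m in spec.marker_positions]
    return ct, contour, markers


def embed_markers(
    ct: VoxelVolume, markers, radius: float, attenuation: float
) -> VoxelVolume:
    """Burn spherical fiducial markers into a copy of ``ct``.

    Voxels whose centres lie within ``radius`` mm of a marker centre are
    set to ``max(existing, attenuation)``; everything else is untouched,
    so the operation is idempotent.  Markers are modelled as spheres; when
    ``radius`` is below the voxel pitch the single nearest voxel is used
    so a marker is never silently lost.
    """
    out = ct.copy()
    lo, hi = ct.world_extent()
    axes = ct.voxel_centres()
    for m in markers:
        m = np.asarray(m, dtype=float)
        if np.any(m < lo) or np.any(m > hi):
            raise ValueError(f"marker {m} lies outside the volume grid")
        d2 = (
            (axes[0][:, None, None] - m[0]) ** 2
            + (axes[1][None, :, None] - m[1]) ** 2
            + (axes[2][None, None, :] - m[2]) ** 2
        )
        ball = d2 <= radius**2
        if not ball.any():
            idx = np.unravel_index(np.argmin(d2), d2.shape)
            ball[idx] = True
        out.values[ball] = np.maximum(out.values[ball], attenuation)
    return out


def default_spec(with_markers: bool = False, n_markers: int = 3) -> PhantomSpec:
    """The package's standard test phantom; markers sit inside the prostate."""
    spec = PhantomSpec()
    if with_markers:
        # fixed tripod arrangement, comfortably interior to the prostate
        offsets = [(-8.0, -5.0, 4.0), (8.0, -4.0, -5.0), (0.0, 7.0, 6.0)]
        spec.marker_positions = [
            tuple(np.add(spec.prostate_center, o)) for o in offsets[:n_markers]
        ]
    return spec
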