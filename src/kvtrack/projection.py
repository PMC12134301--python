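"""Cone-beam forward projection (DRR synthesis) and projective shift mapping.

Geometry convention.  The gantry rotates in the axial x-z plane about the
patient's superior-inferior (y) axis.  At gantry angle ``theta`` (degrees)
the unit vector from isocentre towards the x-ray source is

    e(theta) = (cos theta, 0, sin theta),

so at ``theta = 0`` the source sits on the +x axis at distance SAD from the
isocentre.  The flat detector is perpendicular to the beam axis at distance
SID from the source, with in-plane axes

    u(theta) = (sin theta, 0, -cos theta)   (transverse, reported as AP/LAT)
    v        = (0, 1, 0)                    (superior-inferior)

Under this convention a small 3D displacement (x, y, z) of a point near the
isocentre moves its detector projection by

    (u, v) = SID / (SAD - (x cos t + z sin t)) * (x sin t - z cos t, y),

which is the closed-form mapping implemented by :func:`project_shift`.

Naming note: SAD here is the source-axis (source-isocentre) distance and
SID the source-imager distance, the only reading under which the mapping
above and the SID/SAD = 1.5 isocentre-pixel correction are simultaneously
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._raycast import raymarch
from .volumes import VoxelVolume

__all__ = [
    "BeamGeometry",
    "ProjectionImage",
    "desk_geometry",
    "forward_project",
    "generate_arc",
    "project_shift",
    "pixel_to_isocentre_mm",
]


@dataclass(frozen=True)
class BeamGeometry:
    """Rotational cone-beam parameters.

    ``detector_shape`` is (rows, cols) = (v pixels, u pixels);
    ``detector_pitch`` is mm per detector pixel.  The default pitch of
    0.39 mm reproduces a 0.26 mm pixel at the isocentre plane under the
    default SID/SAD magnification of 1.5.
    """

    SAD: float = 1000.0
    SID: float = 1500.0
    detector_shape: tuple[int, int] = (512, 512)
    detector_pitch: float = 0.39

    def __post_init__(self) -> None:
        if not self.SAD > 0:
            raise ValueError("SAD must be positive")
        if self.SID < self.SAD:
            raise ValueError("SID must be >= SAD (detector beyond the isocentre)")
        if self.detector_pitch <= 0:
            raise ValueError("detector_pitch must be positive")
        if any(int(s) < 1 for s in self.detector_shape):
            raise ValueError("detector_shape must have at least one pixel per axis")

    @property
    def magnification(self) -> float:
        return self.SID / self.SAD

    def source_position(self, angle_deg: float) -> np.ndarray:
        t = np.deg2rad(angle_deg)
        return self.SAD * np.array([np.cos(t), 0.0, np.sin(t)])

    def detector_frame(self, angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(centre, u_axis, v_axis) of the detector plane in patient mm."""
        t = np.deg2rad(angle_deg)
        e = np.array([np.cos(t), 0.0, np.sin(t)])
        centre = self.source_position(angle_deg) - self.SID * e
        u_axis = np.array([np.sin(t), 0.0, -np.cos(t)])
        v_axis = np.array([0.0, 1.0, 0.0])
        return centre, u_axis, v_axis

    def pixel_positions(self, angle_deg: float) -> np.ndarray:
        """World coordinates of every detector pixel centre, shape (rows*cols, 3)."""
        rows, cols = self.detector_shape
        centre, u_axis, v_axis = self.detector_frame(angle_deg)
        u = (np.arange(cols) - (cols - 1) / 2.0) * self.detector_pitch
        v = (np.arange(rows) - (rows - 1) / 2.0) * self.detector_pitch
        uu, vv = np.meshgrid(u, v)  # (rows, cols)
        pts = centre[None, :] + uu.reshape(-1, 1) * u_axis[None, :] + vv.reshape(-1, 1) * v_axis[None, :]
        return pts


def desk_geometry(n: int = 64) -> BeamGeometry:
    """Reduced-resolution geometry for desk-scale runs.

    Keeps the physical panel size of the full 512 x 0.39 mm detector
    (199.68 mm) so the field of view at the isocentre is unchanged; only
    the pixel pitch grows as the pixel count shrinks.
    """
    return BeamGeometry(detector_shape=(n, n), detector_pitch=0.39 * 512 / n)


@dataclass
class ProjectionImage:
    """A 2D projection: values[row, col] with row ~ v (SI), col ~ u."""

    values: np.ndarray
    pitch: float
    angle: float
    kind: str = "anatomy"  # anatomy | mask | kv

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("projection image must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection values must be finite")
        if self.kind in ("anatomy", "mask") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} projection must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def forward_project(
    volume: VoxelVolume, geom: BeamGeometry, angle: float, step: float | None = None,
    kind: str = "anatomy",
) -> ProjectionImage:
    """Compute the DRR of ``volume`` at gantry ``angle`` (degrees).

    Each pixel is the line integral of attenuation (units: attenuation x mm)
    along the source-to-pixel ray, sampled at uniform steps of at most half
    the minimum voxel spacing with trilinear interpolation; rays that miss
    the volume give 0.
    """
    _check_volume_fits(volume, geom)
    if step is None:
        step = float(np.min(volume.spacing)) / 2.0
    rows, cols = geom.detector_shape
    pts = np.ascontiguousarray(geom.pixel_positions(angle))
    out = np.zeros(rows * cols)
    raymarch(
        np.ascontiguousarray(volume.values),
        geom.source_position(angle),
        pts,
        step,
        volume.origin,
        volume.spacing,
        out,
    )
    return ProjectionImage(out.reshape(rows, cols), geom.detector_pitch, float(angle) % 360.0, kind)


def generate_arc(
    volume: VoxelVolume, geom: BeamGeometry, angle_step: float = 1.0,
    step: float | None = None, kind: str = "anatomy",
) -> list[ProjectionImage]:
    """DRRs over a full rotation at ``angle_step`` degree increments.

    Produces images at angles 0, step, ..., 360 - step; ``angle_step`` must
    divide 360 so the arc closes.
    """
    if angle_step <= 0 or abs(360.0 / angle_step - round(360.0 / angle_step)) > 1e-9:
        raise ValueError(f"angle_step must evenly divide 360, got {angle_step}")
    n = int(round(360.0 / angle_step))
    return [forward_project(volume, geom, i * angle_step, step=step, kind=kind) for i in range(n)]


def project_shift(shift3d, angle: float, geom: BeamGeometry) -> np.ndarray:
    """Map a 3D shift (x, y, z) mm at the isocentre to a 2D detector shift.

    Implements the cone-beam projective mapping described in the module
    docstring: the transverse detector shift picks up the in-plane
    component ``x sin t - z cos t`` and the SI shift the ``y`` component,
    both magnified by ``SID / (SAD - (x cos t + z sin t))``.  Returns
    ``(u, v)`` in mm at the detector plane.
    """
    x, y, z = (float(c) for c in shift3d)
    t = np.deg2rad(angle)
    along = x * np.cos(t) + z * np.sin(t)
    if abs(along) >= geom.SAD:
        raise ValueError("shift places the point at or behind the x-ray source")
    scale = geom.SID / (geom.SAD - along)
    return np.array([scale * (x * np.sin(t) - z * np.cos(t)), scale * y])


def pixel_to_isocentre_mm(value_px, geom: BeamGeometry) -> np.ndarray | float:
    """Rescale a detector-pixel measurement to mm at the isocentre plane.

    The detector pitch is demagnified by SAD/SID; with the defaults
    (pitch 0.39 mm, magnification 1.5) one detector pixel corresponds to
    0.26 mm of motion at the isocentre.
    """
    return np.asarray(value_px, dtype=float) * geom.detector_pitch * geom.SAD / geom.SID


def _check_volume_fits(volume: VoxelVolume, geom: BeamGeometry) -> None:
    lo, hi = volume.world_extent()
    corner_r = float(np.max(np.abs(np.stack([lo, hi]))))
    # conservative: the volume's bounding sphere must not reach the source
    if np.sqrt(3.0) * corner_r >= geom.SAD:
        raise ValueError("volume does not fit between the source and the isocentre")
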