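"""Ground-truth construction utilities.

Three ingredients turn clean phantom projections into realistic test data:

* harmonic inpainting of fiducial-marker footprints (discrete Laplace
  equation with Dirichlet boundary values taken from the surrounding
  pixels), in 2D for projections and 3D for volumes;
* Poisson photon noise;
* sub-pixel rigid 2D shifts of kV-like images, used to build the
  "markerless-style" ground truth from a known 3D couch shift.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.ndimage import binary_dilation, shift as nd_shift
from scipy.sparse.linalg import cg, spsolve

from .projection import BeamGeometry, ProjectionImage, project_shift
from .volumes import VoxelVolume

__all__ = [
    "inpaint_regions",
    "add_poisson_noise",
    "shift_image",
    "mask_markers_3d",
    "marker_footprint_2d",
]

_DIRECT_SOLVE_LIMIT = 20000  # unknowns; above this fall back to CG


def _solve_laplace(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace ``values[mask]`` with the solution of the discrete Laplace
    equation (2*ndim-point stencil) with Dirichlet data from unmasked
    neighbours.  Works for any dimensionality; here used in 2D and 3D.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask must have the same shape as the image/volume")
    if not mask.any():
        return values.copy()
    # boundary condition undefined if the masked region touches the border
    border = np.zeros_like(mask)
    for ax in range(mask.ndim):
        sl0 = [slice(None)] * mask.ndim
        sl0[ax] = 0
        sl1 = [slice(None)] * mask.ndim
        sl1[ax] = -1
        border[tuple(sl0)] = True
        border[tuple(sl1)] = True
    if (mask & border).any():
        raise ValueError("masked region touches the border; Dirichlet data undefined")

    idx = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    idx[mask] = np.arange(coords.shape[0])
    n = coords.shape[0]
    ndim = mask.ndim
    rows, cols, data = [], [], []
    b = np.zeros(n)
    eye = np.eye(ndim, dtype=np.int64)
    for k in range(n):
        c = coords[k]
        rows.append(k)
        cols.append(k)
        data.append(2.0 * ndim)
        for ax in range(ndim):
            for sgn in (-1, 1):
                nb = tuple(c + sgn * eye[ax])
                j = idx[nb]
                if j >= 0:
                    rows.append(k)
                    cols.append(j)
                    data.append(-1.0)
                else:
                    b[k] += values[nb]
    A = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    if n <= _DIRECT_SOLVE_LIMIT:
        x = spsolve(A, b)
    else:
        x, info = cg(A, b, rtol=1e-12, atol=0.0, maxiter=10 * n)
        if info != 0:
            raise RuntimeError("conjugate-gradient Laplace solve did not converge")
    scale = max(float(np.abs(values).max()), 1.0)
    if np.max(np.abs(A @ x - b)) > 1e-6 * scale:
        raise RuntimeError("Laplace solve residual exceeds tolerance")
    out = values.copy()
    out[mask] = x
    return out


def inpaint_regions(image: ProjectionImage, mask: np.ndarray) -> ProjectionImage:
    """Harmonically fill the masked pixels of a projection image.

    Each masked pixel of the output equals the mean of its four
    neighbours (discrete Laplace equation) with Dirichlet boundary given
    by the adjacent unmasked pixels; pixels outside the mask are
    untouched.  The fill inherits the discrete maximum principle: filled
    values never leave the range of their boundary values.
    """
    vals = _solve_laplace(np.asarray(image.values, dtype=np.float64), mask)
    return ProjectionImage(vals, image.pitch, image.angle, image.kind)


def mask_markers_3d(volume: VoxelVolume, markers, radius: float) -> VoxelVolume:
    """Remove spherical marker footprints from a volume by 3D harmonic fill.

    The 6-neighbour analogue of :func:`inpaint_regions`: voxels within
    ``radius`` mm of a marker centre are replaced by the solution of the
    discrete Laplace equation with Dirichlet data from the surrounding
    voxels.  Unmasked voxels are bit-identical to the input.
    """
    lo, hi = volume.world_extent()
    axes = volume.voxel_centres()
    mask = np.zeros(volume.shape, dtype=bool)
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
            ball[np.unravel_index(np.argmin(d2), d2.shape)] = True
        mask |= ball
    vals = _solve_laplace(volume.values.astype(np.float64), mask)
    return VoxelVolume(vals, volume.spacing.copy(), volume.origin.copy())


def add_poisson_noise(
    image: ProjectionImage, photons_at_max: int, rng: np.random.Generator
) -> ProjectionImage:
    """Apply photon-counting noise scaled so the brightest pixel receives
    ``photons_at_max`` expected photons.

    Each pixel value p becomes ``Poisson(p / max * N) * max / N``; the
    expected image is unchanged while the relative noise shrinks as
    1/sqrt(N).  Zero pixels stay exactly zero.
    """
    if photons_at_max <= 0:
        raise ValueError("photons_at_max must be positive")
    vals = np.asarray(image.values, dtype=np.float64)
    if np.any(vals < 0):
        raise ValueError("Poisson noise requires a non-negative image")
    vmax = float(vals.max())
    if vmax == 0.0:
        return ProjectionImage(vals.copy(), image.pitch, image.angle, image.kind)
    lam = vals / vmax * photons_at_max
    noisy = rng.poisson(lam).astype(np.float64) * (vmax / photons_at_max)
    return ProjectionImage(noisy, image.pitch, image.angle, image.kind)


def shift_image(image: ProjectionImage, shift2d) -> ProjectionImage:
    """Translate an image by a (u, v) mm detector shift.

    The shift is converted to detector pixels (u moves columns, v moves
    rows), applied with bilinear interpolation and zero fill.  Integer
    pixel shifts reduce to an exact roll with zero fill.
    """
    du, dv = (float(c) / image.pitch for c in shift2d)
    if abs(du) >= image.shape[1] or abs(dv) >= image.shape[0]:
        raise ValueError("shift exceeds the image extent")
    vals = nd_shift(
        np.asarray(image.values, dtype=np.float64),
        (dv, du),
        order=1,
        mode="constant",
        cval=0.0,
    )
    if image.kind in ("anatomy", "mask"):
        vals = np.clip(vals, 0.0, None)
    return ProjectionImage(vals, image.pitch, image.angle, image.kind)


def marker_footprint_2d(
    markers, geom: BeamGeometry, angle: float, marker_radius: float, dilate: int = 1
) -> np.ndarray:
    """Boolean detector mask covering the projected marker spheres.

    Each marker centre is mapped to the detector via the cone-beam
    projective mapping, its radius magnified accordingly, and the disc
    dilated by ``dilate`` pixels to cover interpolation spill.  With the
    phantom, marker geometry is known exactly, so no image-based marker
    detection is needed.
    """
    rows, cols = geom.detector_shape
    mask = np.zeros((rows, cols), dtype=bool)
    rr = (np.arange(rows) - (rows - 1) / 2.0) * geom.detector_pitch
    cc = (np.arange(cols) - (cols - 1) / 2.0) * geom.detector_pitch
    for m in markers:
        u, v = project_shift(m, angle, geom)
        t = np.deg2rad(angle)
        along = m[0] * np.cos(t) + m[2] * np.sin(t)
        mag = geom.SID / (geom.SAD - along)
        r_det = marker_radius * mag
        d2 = (cc[None, :] - u) ** 2 + (rr[:, None] - v) ** 2
        disc = d2 <= max(r_det, geom.detector_pitch) ** 2
        mask |= disc
    if dilate > 0 and mask.any():
        mask = binary_dilation(mask, iterations=dilate)
    return mask
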