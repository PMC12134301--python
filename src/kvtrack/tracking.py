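"""Inference-time tracking workflow.

For every incoming kV-like projection: run the generator, binarise the
prediction at 10% of the output range, keep the largest 8-connected
region, and report its centroid.  Centroid errors against the ground
truth are rescaled from detector pixels to mm at the isocentre plane
(pixel * pitch * SAD/SID) and decomposed into the transverse (AP/LAT)
and superior-inferior (SI) detector directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .projection import BeamGeometry, ProjectionImage, pixel_to_isocentre_mm

__all__ = ["SegMask2D", "TrackingRecord", "segment", "largest_component", "centroid", "track_arc"]

DEFAULT_THRESHOLD = 0.10
_CONN8 = np.ones((3, 3), dtype=int)


@dataclass
class SegMask2D:
    """Binary segmentation with detector metadata."""

    values: np.ndarray
    pitch: float
    angle: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("segmentation mask must be 2D")

    @property
    def empty(self) -> bool:
        return not self.values.any()


@dataclass
class TrackingRecord:
    """Per-image tracking outcome; errors are predicted minus ground truth."""

    angle: float
    pred_centroid_px: tuple[float, float] | None  # (u=col, v=row)
    gt_centroid_px: tuple[float, float] | None
    error_aplat_mm: float
    error_si_mm: float
    dsc: float
    msd_mm: float
    empty_prediction: bool = False
    multi_region: bool = False


def segment(generator, kv: ProjectionImage, threshold: float = DEFAULT_THRESHOLD) -> SegMask2D:
    """Generator prediction binarised at ``threshold`` of the output range.

    The generator output is bounded in [0, 1], so the default 10%
    threshold is an absolute 0.1 cut — an all-noise prediction can
    legitimately produce an empty mask, which is flagged downstream
    rather than rescued.
    """
    from .nn import Tensor  # local import keeps this module lightweight

    x = np.asarray(kv.values, dtype=np.float64)
    out = generator(Tensor(x[None, None, :, :]))
    pred = out.data if isinstance(out, Tensor) else np.asarray(out)
    pred = pred.reshape(x.shape)
    return SegMask2D(pred >= threshold, kv.pitch, kv.angle)


def largest_component(mask: SegMask2D) -> SegMask2D:
    """Keep only the largest 8-connected region.

    Ties are broken towards the component containing the smallest
    row-major pixel index.  An empty mask passes through unchanged.
    """
    if mask.empty:
        return SegMask2D(mask.values.copy(), mask.pitch, mask.angle)
    labels, n = ndimage.label(mask.values, structure=_CONN8)
    if n == 1:
        return SegMask2D(mask.values.copy(), mask.pitch, mask.angle)
    counts = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(counts == counts.max()) + 1
    if len(best) > 1:
        # first tied label encountered in row-major order wins
        flat = labels.ravel()
        hit = flat[np.isin(flat, best).argmax()]
        keep = hit
    else:
        keep = best[0]
    return SegMask2D(labels == keep, mask.pitch, mask.angle)


def centroid(mask: SegMask2D) -> tuple[float, float]:
    """(u, v) = (col, row) mean of member pixel coordinates (pixel centres)."""
    if mask.empty:
        raise ValueError("centroid of an empty mask is undefined")
    rows, cols = np.nonzero(mask.values)
    return float(cols.mean()), float(rows.mean())


def track_arc(
    generator,
    kv_images: list[ProjectionImage],
    gt_masks: list[SegMask2D],
    geom: BeamGeometry,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[TrackingRecord]:
    """Run the full tracking workflow over an arc of images.

    Returns one record per image.  Empty predictions (or empty ground
    truth) produce a flagged record with NaN errors that summary
    statistics exclude.
    """
    from .evaluation import dice, mean_surface_distance

    if len(kv_images) != len(gt_masks):
        raise ValueError("kv_images and gt_masks must be aligned")
    records = []
    for kv, gt in zip(kv_images, gt_masks):
        raw = segment(generator, kv, threshold)
        labels, n_regions = ndimage.label(raw.values, structure=_CONN8)
        pred = largest_component(raw)
        if pred.empty or gt.empty:
            records.append(
                TrackingRecord(
                    angle=kv.angle,
                    pred_centroid_px=None,
                    gt_centroid_px=None if gt.empty else centroid(gt),
                    error_aplat_mm=np.nan,
                    error_si_mm=np.nan,
                    dsc=np.nan,
                    msd_mm=np.nan,
                    empty_prediction=True,
                    multi_region=n_regions > 1,
                )
            )
            continue
        pu, pv = centroid(pred)
        gu, gv = centroid(gt)
        err_u = float(pixel_to_isocentre_mm(pu - gu, geom))
        err_v = float(pixel_to_isocentre_mm(pv - gv, geom))
        records.append(
            TrackingRecord(
                angle=kv.angle,
                pred_centroid_px=(pu, pv),
                gt_centroid_px=(gu, gv),
                error_aplat_mm=err_u,
                error_si_mm=err_v,
                dsc=dice(pred, gt),
                msd_mm=mean_surface_distance(
                    pred, gt, pitch_iso=float(pixel_to_isocentre_mm(1.0, geom))
                ),
                empty_prediction=False,
                multi_region=n_regions > 1,
            )
        )
    return records
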