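"""Quantitative evaluation of the tracking system.

Implements the segmentation-agreement metrics (Dice similarity
coefficient, symmetric mean surface distance), centroid-error summary
statistics (mean, sample SD, mean absolute deviation, 5th/95th
percentiles), Pearson correlation, Bland-Altman agreement analysis, and
per-imager-angle statistics.

Conventions: MAD is the mean of absolute errors (not median-based);
percentiles use linear interpolation between order statistics; MSD is the
symmetric average of the two directed mean boundary distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .tracking import SegMask2D, TrackingRecord

__all__ = [
    "MetricsSummary",
    "dice",
    "mean_surface_distance",
    "summarize",
    "pearson",
    "bland_altman",
    "per_angle_stats",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def dice(a: SegMask2D, b: SegMask2D) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    av, bv = a.values, b.values
    if av.shape != bv.shape:
        raise ValueError("masks must share shape")
    na, nb = int(av.sum()), int(bv.sum())
    if na + nb == 0:
        raise ValueError("Dice of two empty masks is undefined")
    return 2.0 * int((av & bv).sum()) / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Member pixels with at least one non-member 4-neighbour."""
    return mask & ~binary_erosion(mask, structure=_CROSS, border_value=0)


def mean_surface_distance(a: SegMask2D, b: SegMask2D, pitch_iso: float = 1.0) -> float:
    """Symmetric mean surface distance in mm at the isocentre plane.

    Boundaries are 4-connectivity member-edge pixels; distances are
    Euclidean between pixel centres scaled by ``pitch_iso``.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("masks must share shape")
    if not a.values.any() or not b.values.any():
        raise ValueError("mean surface distance requires nonempty masks")
    pa = np.argwhere(_boundary(a.values)).astype(float)
    pb = np.argwhere(_boundary(b.values)).astype(float)
    da = cKDTree(pb).query(pa)[0]
    db = cKDTree(pa).query(pb)[0]
    return 0.5 * (da.mean() + db.mean()) * pitch_iso


@dataclass
class MetricsSummary:
    """Summary statistics per direction plus DSC/MSD distributions."""

    aplat: dict = field(default_factory=dict)  # mean, sd, mad, p5, p95 (mm)
    si: dict = field(default_factory=dict)
    dsc: dict = field(default_factory=dict)  # mean, sd, p5, p95
    msd: dict = field(default_factory=dict)  # mm
    n: int = 0
    dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "aplat": self.aplat,
            "si": self.si,
            "dsc": self.dsc,
            "msd": self.msd,
            "n": self.n,
            "dropped": self.dropped,
        }


def _series_stats(x: np.ndarray, signed: bool = True) -> dict:
    out = {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "p5": float(np.percentile(x, 5)),
        "p95": float(np.percentile(x, 95)),
    }
    if signed:
        out["mad"] = float(np.mean(np.abs(x)))
    return out


def summarize(records: list[TrackingRecord]) -> MetricsSummary:
    """Aggregate tracking records; flagged (empty-prediction) records are
    excluded from statistics and counted as dropped frames."""
    good = [r for r in records if not r.empty_prediction]
    if not good:
        raise ValueError("no unflagged records to summarise")
    ap = np.array([r.error_aplat_mm for r in good])
    si = np.array([r.error_si_mm for r in good])
    ds = np.array([r.dsc for r in good])
    ms = np.array([r.msd_mm for r in good])
    return MetricsSummary(
        aplat=_series_stats(ap),
        si=_series_stats(si),
        dsc=_series_stats(ds, signed=False),
        msd=_series_stats(ms, signed=False),
        n=len(good),
        dropped=len(records) - len(good),
    )


def pearson(a, b) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation undefined for constant series")
    return float(stats.pearsonr(a, b)[0])


def bland_altman(motion, error) -> tuple[float, float, float]:
    """Bland-Altman agreement between observed motion and centroid error.

    Returns (bias, lower limit, upper limit) where bias is the mean
    difference and the limits of agreement are bias +/- 1.96 SD of the
    differences.
    """
    motion = np.asarray(motion, dtype=float)
    error = np.asarray(error, dtype=float)
    if motion.shape != error.shape or motion.size < 3:
        raise ValueError("series must have equal length >= 3")
    diff = error - motion
    bias = float(diff.mean())
    sd = float(np.std(diff, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def per_angle_stats(records: list[TrackingRecord], bin_deg: float = 1.0) -> pd.DataFrame:
    """Per-imager-angle means and 5/95th percentiles.

    One row per ``bin_deg`` bin over [0, 360); bins without samples are
    reported with NaN statistics and n = 0 (the number of samples per
    angle is generally variable).
    """
    if bin_deg <= 0:
        raise ValueError("bin_deg must be positive")
    n_bins = int(np.ceil(360.0 / bin_deg))
    rows = []
    good = [r for r in records if not r.empty_prediction]
    angles = np.array([r.angle % 360.0 for r in good])
    bins = (angles // bin_deg).astype(int) if good else np.array([], dtype=int)
    for b in range(n_bins):
        sel = [g for g, k in zip(good, bins) if k == b]
        row = {"angle_lo": b * bin_deg, "angle_hi": (b + 1) * bin_deg, "n": len(sel)}
        for name, get in (
            ("aplat", lambda r: r.error_aplat_mm),
            ("si", lambda r: r.error_si_mm),
            ("dsc", lambda r: r.dsc),
        ):
            vals = np.array([get(r) for r in sel])
            if vals.size:
                row[f"{name}_mean"] = float(vals.mean())
                row[f"{name}_p5"] = float(np.percentile(vals, 5))
                row[f"{name}_p95"] = float(np.percentile(vals, 95))
            else:
                row[f"{name}_mean"] = row[f"{name}_p5"] = row[f"{name}_p95"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
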