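"""Gel densitometry: lane traces, size calibration, and replotting vs size.

A telomere restriction fragment (TRF) Southern blot is quantified by reading a
one-dimensional intensity trace down each lane, calibrating migration distance
against a molecular-weight marker lane, and replotting the trace as a function
of estimated fragment size.  Median telomere length and related statistics are
then computed from the size-indexed trace (see :mod:`teloquant.trf`).

Coordinate conventions
----------------------
* migration distance in mm from the well (0 = well, increasing down the gel);
* fragment sizes in kb when reported, bp in marker tables;
* the semi-log mobility approximation ``distance = a - b * log10(size_kb)``
  underlies the ``"semilog"`` calibration kind; the default ``"interp"`` kind
  is a monotone piecewise-linear interpolant in (distance, log10 size) that
  tolerates gel nonlinearity.

Replotting intensity against size is a pure relabeling of the x-axis: no
Jacobian reweighting is applied by default, so total intensity is conserved
sample-by-sample.  A Jacobian-corrected variant is available behind a flag for
methodological comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LaneProfile",
    "CalibrationCurve",
    "TelomereSizeProfile",
    "extract_lane_profile",
    "subtract_background",
    "fit_calibration",
    "distance_to_size",
    "remap_profile",
    "read_lane_tsv",
    "read_marker_csv",
]

#: Allowed extrapolation beyond the marker span, as a fraction of the span.
EXTRAPOLATION_MARGIN = 0.10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LaneProfile:
    """1D densitometric trace: migration distance (mm) vs intensity (a.u.)."""

    distance_mm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance_mm.shape != self.intensity.shape:
            raise ValueError("distance_mm and intensity must have equal length")
        if self.distance_mm.size < 2:
            raise ValueError("profile needs at least 2 samples")
        if np.any(np.diff(self.distance_mm) <= 0):
            raise ValueError("distances must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance_mm": self.distance_mm, "intensity": self.intensity}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class TelomereSizeProfile:
    """Intensity re-indexed by estimated fragment size (kb, ascending)."""

    size_kb: np.ndarray
    intensity: np.ndarray
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.size_kb = np.asarray(self.size_kb, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.size_kb.shape != self.intensity.shape:
            raise ValueError("size_kb and intensity must have equal length")
        if np.any(np.diff(self.size_kb) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def total_signal(self) -> float:
        return float(self.intensity.sum())


@dataclass
class CalibrationCurve:
    """Monotone mapping between migration distance and log10 fragment size.

    ``kind="semilog"`` stores the least-squares line
    ``distance = a_mm - b_mm_per_decade * log10(size_kb)``;
    ``kind="interp"`` stores marker knots and interpolates log10(size)
    piecewise-linearly in distance, extrapolating linearly at both ends.
    The valid distance range is the marker span widened by
    ``EXTRAPOLATION_MARGIN`` on each side.
    """

    kind: str
    valid_range_mm: tuple[float, float]
    a_mm: Optional[float] = None
    b_mm_per_decade: Optional[float] = None
    knot_distance_mm: Optional[np.ndarray] = field(default=None, repr=False)
    knot_log10_size_kb: Optional[np.ndarray] = field(default=None, repr=False)

    def size_kb(self, distance_mm) -> np.ndarray:
        """Fragment size (kb) at a migration distance (mm)."""
        d = np.asarray(distance_mm, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite migration distance")
        if self.kind == "semilog":
            log_size = (self.a_mm - d) / self.b_mm_per_decade
        else:
            log_size = _interp_linear_extrap(
                d, self.knot_distance_mm, self.knot_log10_size_kb
            )
        out = 10.0 ** log_size
        return out if out.ndim else float(out)

    def distance_mm_at(self, size_kb) -> np.ndarray:
        """Inverse mapping: migration distance (mm) of a fragment size (kb)."""
        s = np.asarray(size_kb, dtype=float)
        if np.any(s <= 0):
            raise ValueError("size must be positive")
        log_size = np.log10(s)
        if self.kind == "semilog":
            out = self.a_mm - self.b_mm_per_decade * log_size
        else:
            # knots are increasing in distance, decreasing in log size
            out = _interp_linear_extrap(
                log_size,
                self.knot_log10_size_kb[::-1],
                self.knot_distance_mm[::-1],
            )
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "valid_range_mm": list(self.valid_range_mm)}
        if self.kind == "semilog":
            d.update(a_mm=self.a_mm, b_mm_per_decade=self.b_mm_per_decade)
        else:
            d.update(
                knot_distance_mm=self.knot_distance_mm.tolist(),
                knot_log10_size_kb=self.knot_log10_size_kb.tolist(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        kw = dict(d)
        kw["valid_range_mm"] = tuple(kw["valid_range_mm"])
        for key in ("knot_distance_mm", "knot_log10_size_kb"):
            if kw.get(key) is not None:
                kw[key] = np.asarray(kw[key], dtype=float)
        return cls(**kw)


def _interp_linear_extrap(x, xp, fp) -> np.ndarray:
    """np.interp with linear (not clamped) extrapolation at both ends."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    xp = np.asarray(xp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + slope * (x[lo] - xp[0])
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return y


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_lane_profile(
    image: np.ndarray,
    lane_left_px: int,
    lane_right_px: int,
    well_row_px: int,
    mm_per_px: float,
) -> LaneProfile:
    """Collapse a lane of a gel image into a 1D trace.

    Sums pixel intensities row-wise across the lane width
    ``[lane_left_px, lane_right_px)``; migration distance is measured from
    ``well_row_px`` downward at ``mm_per_px`` mm per pixel.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected 2D image, got ndim={image.ndim}")
    n_rows, n_cols = image.shape
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if not (0 <= lane_left_px < lane_right_px <= n_cols):
        raise ValueError(
            f"lane bounds [{lane_left_px}, {lane_right_px}) invalid for width {n_cols}"
        )
    if not (0 <= well_row_px < n_rows):
        raise ValueError(f"well_row_px={well_row_px} outside image height {n_rows}")

    rows = np.arange(well_row_px, n_rows)
    intensity = image[rows, lane_left_px:lane_right_px].astype(float).sum(axis=1)
    distance = (rows - well_row_px).astype(float) * mm_per_px
    # the well row itself is distance 0; need strictly increasing -> keep as is
    return LaneProfile(distance_mm=distance, intensity=np.clip(intensity, 0, None))


def subtract_background(
    profile: LaneProfile,
    method: str = "min",
    window_mm: float = 10.0,
) -> LaneProfile:
    """Remove a constant or slowly-varying baseline from a lane trace.

    ``"min"`` subtracts the global minimum over the trace; ``"rolling-min"``
    subtracts a moving-minimum baseline of width ``window_mm`` (implemented
    as a morphological opening — minimum filter followed by maximum filter —
    so repeated application is a no-op).  Negative results are clipped to
    zero; both methods are idempotent.
    """
    y = profile.intensity
    if method == "min":
        baseline = np.full_like(y, y.min())
    elif method == "rolling-min":
        from scipy import ndimage

        step = float(np.median(np.diff(profile.distance_mm)))
        size = 2 * int(round(window_mm / 2.0 / step)) + 1
        if size > y.size:
            raise ValueError(
                f"window {window_mm} mm exceeds profile extent "
                f"({profile.distance_mm[-1] - profile.distance_mm[0]:.1f} mm)"
            )
        baseline = ndimage.grey_opening(y, size=size, mode="nearest")
    else:
        raise ValueError(f"unknown background method {method!r}")
    return LaneProfile(
        distance_mm=profile.distance_mm.copy(),
        intensity=np.clip(y - baseline, 0.0, None),
    )


def fit_calibration(markers: pd.DataFrame, kind: str = "interp") -> CalibrationCurve:
    """Build a size calibration curve from a marker table.

    ``markers`` must have columns ``size_bp`` and ``distance_mm`` with at
    least two rows, distinct values, and a jointly monotone relationship
    (larger fragments migrate less far).
    """
    if kind not in ("semilog", "interp"):
        raise ValueError(f"unknown calibration kind {kind!r}")
    required = {"size_bp", "distance_mm"}
    if not required.issubset(markers.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    tbl = markers.sort_values("distance_mm").reset_index(drop=True)
    size = tbl["size_bp"].to_numpy(dtype=float)
    dist = tbl["distance_mm"].to_numpy(dtype=float)
    if len(tbl) < 2:
        raise ValueError("need at least 2 markers for a calibration curve")
    if np.any(np.diff(dist) <= 0) or len(np.unique(size)) != len(size):
        raise ValueError("marker distances and sizes must be distinct")
    # sorted by increasing distance, sizes must strictly decrease
    bad = np.flatnonzero(np.diff(size) >= 0)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            "non-monotone marker table: "
            f"{size[i]:.0f} bp at {dist[i]:.2f} mm vs "
            f"{size[i + 1]:.0f} bp at {dist[i + 1]:.2f} mm"
        )

    span = dist[-1] - dist[0]
    valid = (dist[0] - EXTRAPOLATION_MARGIN * span, dist[-1] + EXTRAPOLATION_MARGIN * span)
    log_kb = np.log10(size / 1000.0)
    if kind == "semilog":
        # distance = a - b*log10(size_kb), least squares
        slope, intercept = np.polyfit(log_kb, dist, 1)
        return CalibrationCurve(
            kind="semilog",
            valid_range_mm=valid,
            a_mm=float(intercept),
            b_mm_per_decade=float(-slope),
        )
    return CalibrationCurve(
        kind="interp",
        valid_range_mm=valid,
        knot_distance_mm=dist,
        knot_log10_size_kb=log_kb,
    )


def distance_to_size(cal: CalibrationCurve, distance_mm) -> np.ndarray:
    """Fragment size (kb) for migration distance(s), warning on extrapolation."""
    d = np.atleast_1d(np.asarray(distance_mm, dtype=float))
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite migration distance")
    lo, hi = cal.valid_range_mm
    if np.any(d < lo) or np.any(d > hi):
        import warnings

        warnings.warn(
            f"distance outside calibration valid range [{lo:.1f}, {hi:.1f}] mm; "
            "extrapolating",
            stacklevel=2,
        )
    out = cal.size_kb(d)
    return out if np.ndim(distance_mm) else float(np.asarray(out).ravel()[0])


def remap_profile(profile: LaneProfile, cal: CalibrationCurve) -> TelomereSizeProfile:
    """Replot a lane trace as intensity vs estimated fragment size.

    Each (distance, intensity) sample is relabeled to (size(distance),
    intensity); samples outside the calibration's valid range are trimmed.
    No Jacobian reweighting is applied, so the per-sample intensity sum is
    conserved exactly over the retained samples.
    """
    d = profile.distance_mm
    lo, hi = cal.valid_range_mm
    keep = (d >= lo) & (d <= hi)
    if not keep.any():
        raise ValueError(
            f"profile ({d[0]:.1f}-{d[-1]:.1f} mm) has no overlap with the "
            f"calibration valid range [{lo:.1f}, {hi:.1f}] mm"
        )
    sizes = np.asarray(cal.size_kb(d[keep]), dtype=float)
    intens = profile.intensity[keep]
    # distance ascending => size descending; report ascending
    order = np.argsort(sizes)
    return TelomereSizeProfile(size_kb=sizes[order], intensity=intens[order])


# ---------------------------------------------------------------------------
# file I/O helpers
# ---------------------------------------------------------------------------

def read_lane_tsv(path) -> LaneProfile:
    """Read a lane trace TSV with columns distance_mm, intensity."""
    df = pd.read_csv(path, sep="\t")
    return LaneProfile(
        distance_mm=df["distance_mm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
    )


def read_marker_csv(path) -> pd.DataFrame:
    """Read a marker table CSV with columns size_bp, distance_mm."""
    return pd.read_csv(path)


def read_gel_image(path) -> np.ndarray:
    """Read a 16-bit grayscale TIFF or PNG gel scan as a 2D float array."""
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(p)
    else:
        from PIL import Image

        img = np.asarray(Image.open(p))
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse RGB scans
        img = img.mean(axis=2)
    return img
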