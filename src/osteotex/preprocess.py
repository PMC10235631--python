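"""Radiograph enhancement, projection-scale normalization and ROI geometry.

The enhancement chain is flat-field correction, then dark-channel-prior
dehazing, then quantile contrast windowing, in that order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from osteotex.errors import (
    CalibrationError,
    DataError,
    DegenerateBackgroundError,
    DegeneratePolygonError,
    ParameterError,
)
from osteotex.image import GrayImage

# dark-channel-prior constants (fixed for reproducibility)
_DCP_WINDOW = 15
_DCP_OMEGA = 0.95
_DCP_T_FLOOR = 0.1
_DCP_TOP_FRACTION = 0.001


@dataclass(frozen=True)
class GeometryCalibration:
    """Source-to-image / source-to-object distances of one exposure."""

    sid_mm: float
    sod_mm: float | None = None

    def __post_init__(self) -> None:
        if self.sid_mm <= 0:
            raise CalibrationError("SID must be positive")
        if self.sod_mm is not None:
            if not (0 < self.sod_mm <= self.sid_mm):
                raise CalibrationError("need 0 < SOD <= SID")

    @property
    def magnification(self) -> float:
        if self.sod_mm is None:
            raise CalibrationError("SOD unknown; estimate it first")
        return self.sid_mm / self.sod_mm


@dataclass(frozen=True)
class ROIPolygon:
    """Simple quadrilateral in pixel coordinates (x=column, y=row)."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) != 4:
            raise DegeneratePolygonError("ROI polygon must have 4 vertices")
        if self.area <= 0:
            raise DegeneratePolygonError("ROI polygon must have positive area")
        from shapely.geometry import Polygon

        if not Polygon(self.vertices).is_valid:
            raise DegeneratePolygonError("ROI polygon is self-intersecting")

    @property
    def area(self) -> float:
        pts = np.asarray(self.vertices, dtype=np.float64)
        x, y = pts[:, 0], pts[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    @property
    def centroid(self) -> tuple[float, float]:
        pts = np.asarray(self.vertices, dtype=np.float64)
        return float(pts[:, 0].mean()), float(pts[:, 1].mean())

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the polygon on a raster of the given shape."""
        from skimage.draw import polygon as sk_polygon

        pts = np.asarray(self.vertices, dtype=np.float64)
        rr, cc = sk_polygon(pts[:, 1], pts[:, 0], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask


def flat_field_correct(img: GrayImage, sigma: float) -> GrayImage:
    """Divide out the low-frequency exposure background.

    The background is a Gaussian blur with standard deviation ``sigma``
    (pixels); the image is multiplied by mean(B)/B and clipped to [0, 1],
    preserving mean intensity.
    """
    if not (sigma > 0):
        raise ParameterError("sigma must be positive")
    background = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="nearest")
    if np.any(background <= 0):
        raise DegenerateBackgroundError("flat-field background contains zeros")
    corrected = img.pixels * (background.mean() / background)
    return img.with_pixels(np.clip(corrected, 0.0, 1.0))


def reduce_haze(img: GrayImage, amount: float) -> GrayImage:
    """Blend a simplified dark-channel-prior dehaze into the image.

    amount=0 returns the input; amount=1 returns the fully dehazed image.
    """
    if not (0.0 <= amount <= 1.0):
        raise ParameterError("amount must lie in [0, 1]")
    if amount == 0.0:
        return img.with_pixels(img.pixels.copy())
    pix = img.pixels
    dark = ndimage.minimum_filter(pix, size=_DCP_WINDOW, mode="nearest")
    k = max(1, int(round(_DCP_TOP_FRACTION * dark.size)))
    top = np.argpartition(dark.ravel(), -k)[-k:]
    atmo = float(pix.ravel()[top].mean())
    if atmo <= 1e-12:
        dehazed = pix
    else:
        t = np.maximum(1.0 - _DCP_OMEGA * dark / atmo, _DCP_T_FLOOR)
        dehazed = (pix - atmo) / t + atmo
    out = amount * dehazed + (1.0 - amount) * pix
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def stretch_window(img: GrayImage, clip: float) -> GrayImage:
    """Linear contrast window between the clip and (1-clip) quantiles."""
    if not (0.0 <= clip < 0.5):
        raise ParameterError("clip must lie in [0, 0.5)")
    pix = img.pixels
    lo = float(np.quantile(pix, clip))
    hi = float(np.quantile(pix, 1.0 - clip))
    if hi <= lo:
        warnings.warn("degenerate image: all intensities equal; returning zeros", stacklevel=2)
        return img.with_pixels(np.zeros_like(pix))
    out = np.clip((pix - lo) / (hi - lo), 0.0, 1.0)
    return img.with_pixels(out)


def estimate_sod(pairs: list[tuple[float, float]], query_sid: float) -> float:
    """Predict a missing SOD from an OLS line through known (SID, SOD) pairs."""
    pts = np.asarray(pairs, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise DataError("need at least 2 (sid, sod) pairs")
    sids, sods = pts[:, 0], pts[:, 1]
    if np.ptp(sids) == 0:
        raise DataError("all SIDs equal: line fit is rank-deficient")
    slope, intercept = np.polyfit(sids, sods, 1)
    return float(slope * query_sid + intercept)


def normalize_magnification(
    img: GrayImage, cal: GeometryCalibration, target_spacing: float
) -> GrayImage:
    """Resample so the object-plane pixel pitch equals ``target_spacing`` mm.

    The object-plane pitch is detector pitch x SOD/SID; resampling is
    bilinear.
    """
    if target_spacing <= 0:
        raise ParameterError("target_spacing must be positive")
    mag = cal.magnification  # raises if SOD unknown; CalibrationError if SOD > SID
    object_spacing = img.spacing_mm / mag
    zoom = object_spacing / target_spacing
    if abs(zoom - 1.0) < 1e-12:
        out = img.pixels.copy()
    else:
        out = ndimage.zoom(img.pixels, zoom, order=1, mode="nearest", grid_mode=True)
        out = np.clip(out, 0.0, 1.0)
    return GrayImage(out, spacing_mm=target_spacing, bit_origin=img.bit_origin, meta=dict(img.meta))


def roi_from_corners(corners) -> ROIPolygon:
    """Central-2/3-of-diagonals ROI from 4 outer corner points.

    ``corners`` are ordered so that (c1, c3) and (c2, c4) are the two
    diagonals of the outer quadrilateral.  Each diagonal contributes its
    points at parameters 1/6 and 5/6; the four breakpoints, ordered by
    angle around their centroid, form the ROI.
    """
    pts = np.asarray(corners, dtype=np.float64)
    if pts.shape != (4, 2):
        raise DataError("expected 4 (x, y) corner points")
    # collinearity check on the outer quadrilateral
    v1 = pts[1] - pts[0]
    v2 = pts[2] - pts[0]
    v3 = pts[3] - pts[0]
    cross = lambda a, b: a[0] * b[1] - a[1] * b[0]  # noqa: E731
    if abs(cross(v1, v2)) < 1e-12 and abs(cross(v1, v3)) < 1e-12:
        raise DegeneratePolygonError("corners are collinear")
    breaks = []
    for i, j in ((0, 2), (1, 3)):
        for t in (1.0 / 6.0, 5.0 / 6.0):
            breaks.append(pts[i] + t * (pts[j] - pts[i]))
    breaks = np.asarray(breaks)
    center = breaks.mean(axis=0)
    order = np.argsort(np.arctan2(breaks[:, 1] - center[1], breaks[:, 0] - center[0]))
    ordered = breaks[order]
    return ROIPolygon(tuple(map(tuple, ordered)))


def load_roi_json(path: str | Path) -> ROIPolygon:
    """Read ``{"corners": [[x, y], ...]}`` (0-based pixel coordinates)."""
    with open(path) as fh:
        payload = json.load(fh)
    return roi_from_corners(payload["corners"])


def enhance(
    img: GrayImage, flatfield_sigma: float = 20.0, dehaze_amount: float = 0.05, clip: float = 0.001
) -> GrayImage:
    """Full enhancement chain: flat-field, dehaze, contrast window."""
    out = flat_field_correct(img, flatfield_sigma)
    out = reduce_haze(out, dehaze_amount)
    return stretch_window(out, clip)
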