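"""Grayscale raster container and file I/O.

Images are carried as float64 rasters in [0, 1] together with the physical
pixel pitch.  PNG/TIFF readers are backed by :mod:`imageio`; DICOM reading
is available when ``pydicom`` is installed (``pip install osteotex[dicom]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from osteotex.errors import DataError

#: DICOM tags consulted when loading projection radiographs.
DICOM_TAGS = ("DistanceSourceToDetector", "DistanceSourceToPatient", "ImagerPixelSpacing")


@dataclass
class GrayImage:
    """A 2-D intensity raster in [0, 1] with isotropic pixel pitch.

    Parameters
    ----------
    pixels:
        2-D float array, finite, values in [0, 1], at least 16x16.
    spacing_mm:
        Physical pixel pitch in millimetres (isotropic, > 0).
    bit_origin:
        Bit depth of the source data (8 or 16); informational.
    meta:
        Free-form provenance (generator bookkeeping, DICOM tags, ...).
    """

    pixels: np.ndarray
    spacing_mm: float = 1.0
    bit_origin: int = 8
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DataError("pixels must be a 2-D array")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise DataError("image must be at least 16x16 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("pixels must be finite")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise DataError("pixels must lie in [0, 1]")
        if not (self.spacing_mm > 0):
            raise DataError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Copy of this image with replaced pixel raster (same metadata)."""
        return GrayImage(pixels, self.spacing_mm, self.bit_origin, dict(self.meta))


def as_pixels(img: "GrayImage | np.ndarray") -> np.ndarray:
    """Accept either a GrayImage or a bare 2-D array; return float64 pixels."""
    if isinstance(img, GrayImage):
        return img.pixels
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise DataError("expected a 2-D raster")
    if not np.all(np.isfinite(arr)):
        raise DataError("raster must be finite")
    return arr


def quantize256(img: "GrayImage | np.ndarray") -> np.ndarray:
    """Quantize a [0, 1] raster to integer gray levels 0..255."""
    pix = as_pixels(img)
    return np.clip(np.round(pix * 255.0), 0, 255).astype(np.int64)


def load_image(path: str | Path) -> GrayImage:
    """Load a grayscale radiograph from PNG/TIFF or DICOM.

    For DICOM the tags ``DistanceSourceToDetector``,
    ``DistanceSourceToPatient`` and ``ImagerPixelSpacing`` are copied into
    ``meta`` when present.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _load_dicom(path)
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # collapse RGB(A) to luminance
        raw = raw[..., :3].mean(axis=-1)
    if raw.dtype == np.uint16:
        bit, denom = 16, 65535.0
    elif raw.dtype == np.uint8:
        bit, denom = 8, 255.0
    else:
        bit, denom = 16, float(max(raw.max(), 1))
    return GrayImage(raw.astype(np.float64) / denom, bit_origin=bit)


def _load_dicom(path: Path) -> GrayImage:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise DataError(
            "reading DICOM requires the optional 'pydicom' dependency "
            "(pip install osteotex[dicom])"
        ) from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    pix = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    meta: dict[str, Any] = {}
    for tag in DICOM_TAGS:
        if hasattr(ds, tag):
            meta[tag] = ds.data_element(tag).value
    spacing = 1.0
    if "ImagerPixelSpacing" in meta:
        spacing = float(meta["ImagerPixelSpacing"][0])
    return GrayImage(pix, spacing_mm=spacing, bit_origin=int(getattr(ds, "BitsStored", 16)), meta=meta)


def save_image_png16(img: "GrayImage | np.ndarray", path: str | Path) -> None:
    """Write a [0, 1] raster (or any finite map, min-max scaled) as 16-bit PNG."""
    import imageio.v3 as iio

    arr = as_pixels(img).astype(np.float64)
    lo, hi = float(np.nanmin(arr)), float(np.nanmax(arr))
    scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
    scaled = np.nan_to_num(scaled, nan=0.0)
    iio.imwrite(Path(path), np.round(scaled * 65535).astype(np.uint16))
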