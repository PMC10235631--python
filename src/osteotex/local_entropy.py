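"""Pixel-wise Shannon entropy of local gray-level-range observations.

A small disk (radius ``r_measure``) yields one integer observation per
pixel: the max-min span of quantized gray levels.  A larger disk (radius
``r_count``) collects the observations whose empirical distribution gives
the local entropy in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from osteotex._stats import HistogramSummary, summarize_distribution
from osteotex.errors import DataError, EmptyResultError, ParameterError
from osteotex.fractal import disk_footprint, disk_offsets
from osteotex.image import GrayImage, quantize256


@dataclass
class EntropyResult:
    """Local-range observations and the per-pixel entropy map."""

    range_map: np.ndarray
    entropy_map: np.ndarray
    r_measure: int
    r_count: int
    valid_mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.entropy_map[self.valid_mask]


def local_range_map(img: GrayImage | np.ndarray, r_measure: int) -> np.ndarray:
    """Integer max-min gray span over the disk around each pixel.

    Boundary pixels use the in-image portion of their disk.
    """
    if r_measure < 1:
        raise ParameterError("r_measure must be >= 1")
    levels = quantize256(img)
    h, w = levels.shape
    vmax = np.full((h, w), np.iinfo(np.int64).min, dtype=np.int64)
    vmin = np.full((h, w), np.iinfo(np.int64).max, dtype=np.int64)
    for di, dj in disk_offsets(r_measure):
        src_r = slice(max(0, di), min(h, h + di))
        src_c = slice(max(0, dj), min(w, w + dj))
        dst_r = slice(max(0, -di), min(h, h - di))
        dst_c = slice(max(0, -dj), min(w, w - dj))
        window = levels[src_r, src_c]
        np.maximum(vmax[dst_r, dst_c], window, out=vmax[dst_r, dst_c])
        np.minimum(vmin[dst_r, dst_c], window, out=vmin[dst_r, dst_c])
    return vmax - vmin


def entropy_map(
    ranges: np.ndarray, mask: np.ndarray | None, r_count: int, r_measure: int = 1
) -> EntropyResult:
    """Shannon entropy (bits) of range observations in the counting disk.

    Only pixels whose counting disk lies entirely inside the mask (and the
    image) are valid.
    """
    ranges = np.asarray(ranges)
    if ranges.ndim != 2:
        raise DataError("range map must be 2-D")
    if r_count <= r_measure:
        raise ParameterError("r_count must exceed r_measure")
    if mask is None:
        mask = np.ones(ranges.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ranges.shape:
        raise DataError("mask shape must match range map shape")

    footprint = disk_footprint(r_count)
    valid = ndimage.binary_erosion(mask, structure=footprint, border_value=0)
    if not valid.any():
        raise EmptyResultError("no pixel has a complete counting disk inside the ROI")

    n = int(footprint.sum())
    kernel = footprint.astype(np.float64)
    ent = np.zeros(ranges.shape, dtype=np.float64)
    # counts per distinct observation value via exact integer-valued convolution
    for v in np.unique(ranges[mask]):
        indicator = (ranges == v).astype(np.float64)
        counts = ndimage.correlate(indicator, kernel, mode="constant", cval=0.0)
        counts = np.round(counts)  # sums of 0/1 are exact; round kills fp dust
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(counts > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        ent += term
    ent = np.where(valid, ent, np.nan)
    return EntropyResult(
        range_map=ranges,
        entropy_map=ent,
        r_measure=r_measure,
        r_count=r_count,
        valid_mask=valid,
    )


def local_entropy_result(
    img: GrayImage | np.ndarray, mask: np.ndarray | None, r_measure: int, r_count: int
) -> EntropyResult:
    """Convenience wrapper: range map then entropy map."""
    ranges = local_range_map(img, r_measure)
    return entropy_map(ranges, mask, r_count, r_measure=r_measure)


def entropy_distribution_stats(res: EntropyResult) -> HistogramSummary:
    """Histogram summary of valid entropy values (no 16-bit entropy term)."""
    values = res.values
    if values.size < 2:
        raise EmptyResultError("need at least 2 valid pixels")
    return summarize_distribution(values, with_entropy16=False)
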