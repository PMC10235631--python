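"""Offset-averaged gray-scale differential box-counting lacunarity.

Box mass is the differential box count of the max-min gray span inside
each r x r box; lacunarity of one grid placement is E[M^2]/E[M]^2, and the
reported value averages all r^2 grid offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from osteotex.errors import DataError, EmptyResultError, ParameterError
from osteotex.image import GrayImage, quantize256


@dataclass
class LacunarityResult:
    """Per-offset and offset-averaged lacunarity at one box size."""

    box_size: int
    per_offset: np.ndarray  # Lambda_gamma for each of the G = r^2 offsets
    mean_lac: float
    n_offsets: int


def dbc_mass_grid(
    img: GrayImage | np.ndarray,
    r: int,
    offset: tuple[int, int],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Differential box-counting masses on one grid placement.

    The image is quantized to 256 gray levels; boxes are non-overlapping
    r x r squares starting at (dx, dy) = ``offset``; box height is
    h = 256 * r / min(W, H); mass M = floor(max/h) - floor(min/h) + 1.
    Boxes straddling the mask (ROI) boundary are dropped.  Returns the 1-D
    array of masses of the complete boxes.
    """
    levels = quantize256(img)
    h_img, w_img = levels.shape
    if not (2 <= r <= min(h_img, w_img) // 2):
        raise ParameterError("box size must satisfy 2 <= r <= min(H, W)/2")
    dx, dy = offset
    if not (0 <= dx < r and 0 <= dy < r):
        raise ParameterError("offset components must lie in [0, r)")
    n_by = (h_img - dy) // r
    n_bx = (w_img - dx) // r
    if n_by < 1 or n_bx < 1:
        raise EmptyResultError("no complete box fits the image at this offset")
    crop = levels[dy : dy + n_by * r, dx : dx + n_bx * r]
    blocks = crop.reshape(n_by, r, n_bx, r)
    box_max = blocks.max(axis=(1, 3))
    box_min = blocks.min(axis=(1, 3))
    height = 256.0 * r / min(h_img, w_img)
    masses = (
        np.floor(box_max / height) - np.floor(box_min / height) + 1
    ).astype(np.int64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != levels.shape:
            raise DataError("mask shape must match image shape")
        mcrop = mask[dy : dy + n_by * r, dx : dx + n_bx * r]
        inside = mcrop.reshape(n_by, r, n_bx, r).all(axis=(1, 3))
        masses = masses[inside]
        if masses.size == 0:
            raise EmptyResultError("no complete box lies inside the ROI")
        return masses.ravel()
    return masses.ravel()


def lacunarity_single_offset(masses: np.ndarray) -> float:
    """Lacunarity E[M^2]/E[M]^2 of one grid of box masses."""
    m = np.asarray(masses, dtype=np.float64).ravel()
    if m.size == 0:
        raise EmptyResultError("empty mass grid")
    mu = m.mean()
    return float(np.mean(m * m) / (mu * mu))


def mean_lacunarity(
    img: GrayImage | np.ndarray, r: int, mask: np.ndarray | None = None
) -> LacunarityResult:
    """Lacunarity averaged over all r^2 grid offsets."""
    per_offset = np.empty(r * r, dtype=np.float64)
    idx = 0
    for dy in range(r):
        for dx in range(r):
            per_offset[idx] = lacunarity_single_offset(
                dbc_mass_grid(img, r, (dx, dy), mask=mask)
            )
            idx += 1
    return LacunarityResult(
        box_size=r,
        per_offset=per_offset,
        mean_lac=float(per_offset.mean()),
        n_offsets=r * r,
    )
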