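"""Per-image extraction of the 11 texture features.

Feature order: fd_mode, fd_sigma, fd_skewness, fd_kurtosis, fd_entropy,
lac_A, lac_B, ent_mode, ent_sigma, ent_skewness, ent_kurtosis.
"""

from __future__ import annotations

import numpy as np

from osteotex.errors import EmptyResultError
from osteotex.fractal import (
    ScaleSeries,
    fd_distribution_stats,
    pixelwise_fd,
    residual_filter,
)
from osteotex.image import GrayImage
from osteotex.lacunarity import mean_lacunarity
from osteotex.local_entropy import entropy_distribution_stats, local_entropy_result


def fd_stats_vector(
    img: GrayImage | np.ndarray,
    scales: ScaleSeries,
    mask: np.ndarray | None = None,
    keep: float = 0.8,
) -> list[float]:
    """[mode, sigma, skewness, kurtosis, shannon_bits] of the FD map."""
    res = residual_filter(pixelwise_fd(img, mask, scales), keep)
    if res.values.size < 2:
        raise EmptyResultError("fewer than 2 retained FD pixels")
    s = fd_distribution_stats(res)
    return [s.mode, s.sigma, s.skewness, s.kurtosis, s.shannon_bits]


def entropy_stats_vector(
    img: GrayImage | np.ndarray,
    r_measure: int,
    r_count: int,
    mask: np.ndarray | None = None,
) -> list[float]:
    """[mode, sigma, skewness, kurtosis] of the local-entropy map."""
    res = local_entropy_result(img, mask, r_measure, r_count)
    s = entropy_distribution_stats(res)
    return [s.mode, s.sigma, s.skewness, s.kurtosis]


def lac_scalar(img: GrayImage | np.ndarray, r: int, mask: np.ndarray | None = None) -> float:
    """Offset-averaged lacunarity at one box size."""
    return mean_lacunarity(img, r, mask=mask).mean_lac


def extract_features(
    img: GrayImage | np.ndarray,
    mask: np.ndarray | None = None,
    fd_range: tuple[int, int] = (1, 4),
    ent_radii: tuple[int, int] = (1, 6),
    lac_sizes: tuple[int, int] = (3, 4),
    keep: float = 0.8,
) -> dict[str, float]:
    """All 11 features of one image, NaN-flagging families that degenerate.

    A constant image, for instance, has zero surface area everywhere, so
    its FD features are NaN while lacunarity is exactly 1 and the entropy
    statistics are 0.
    """
    out: dict[str, float] = {}
    try:
        fd = fd_stats_vector(img, ScaleSeries(*fd_range), mask=mask, keep=keep)
    except EmptyResultError:
        fd = [float("nan")] * 5
    out["fd_mode"], out["fd_sigma"], out["fd_skewness"], out["fd_kurtosis"], out["fd_entropy"] = fd
    out["lac_A"] = lac_scalar(img, lac_sizes[0], mask=mask)
    out["lac_B"] = lac_scalar(img, lac_sizes[1], mask=mask)
    ent = entropy_stats_vector(img, ent_radii[0], ent_radii[1], mask=mask)
    out["ent_mode"], out["ent_sigma"], out["ent_skewness"], out["ent_kurtosis"] = ent
    return out
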