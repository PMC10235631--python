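"""Shared distribution-summary machinery for texture-map histograms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from osteotex.errors import DataError

BIN_WIDTH = 0.005
MODE_WINDOW = 0.011
MODE_STEP = 0.001


@dataclass(frozen=True)
class HistogramSummary:
    """Summary statistics of a per-pixel texture-value distribution.

    ``mode`` is the center of the sliding window (width 0.011, step 0.001)
    that maximizes the mean count of 0.005-wide histogram bins whose centers
    fall inside the window.  ``sigma``/``skewness``/``kurtosis`` are moments
    of the raw values (kurtosis in the non-excess convention, so a Gaussian
    scores 3).  ``shannon_bits`` is the entropy of the values linearly
    rescaled to 16-bit unsigned integers over their min-max range.
    """

    mode: float
    sigma: float
    skewness: float
    kurtosis: float
    shannon_bits: float
    bin_width: float = BIN_WIDTH
    moments_defined: bool = True


def sliding_window_mode(
    values: np.ndarray,
    bin_width: float = BIN_WIDTH,
    window: float = MODE_WINDOW,
    step: float = MODE_STEP,
) -> float:
    """Mode of a histogram smoothed by a sliding mean-count window.

    Window centers sit on a `step` grid spanning [min, max]; ties resolve
    to the smallest center.
    """
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return lo
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    centers = (edges[:-1] + edges[1:]) / 2.0
    n_pos = int(np.floor((hi - lo) / step)) + 1
    win_centers = lo + step * np.arange(n_pos)
    # membership: bin center within half a window of the window center
    inside = np.abs(centers[None, :] - win_centers[:, None]) <= window / 2.0 + 1e-12
    n_in = inside.sum(axis=1)
    sums = inside @ counts
    with np.errstate(invalid="ignore"):
        means = np.where(n_in > 0, sums / np.maximum(n_in, 1), -np.inf)
    return float(win_centers[int(np.argmax(means))])


def shannon_bits_16bit(values: np.ndarray) -> float:
    """Shannon entropy (bits) of values min-max rescaled to uint16 codes."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return 0.0
    codes = np.round((v - lo) / (hi - lo) * 65535.0).astype(np.int64)
    counts = np.bincount(codes)
    p = counts[counts > 0] / v.size
    return float(-np.sum(p * np.log2(p)))


def summarize_distribution(values: np.ndarray, with_entropy16: bool = False) -> HistogramSummary:
    """Full distribution summary used for both FD and entropy maps."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise DataError("need at least 2 values to summarize a distribution")
    if not np.all(np.isfinite(v)):
        raise DataError("distribution values must be finite")
    mode = sliding_window_mode(v)
    sigma = float(np.std(v, ddof=1))
    if sigma == 0.0:
        return HistogramSummary(
            mode=float(v[0]), sigma=0.0, skewness=0.0, kurtosis=0.0,
            shannon_bits=0.0, moments_defined=False,
        )
    mu = v.mean()
    m2 = np.mean((v - mu) ** 2)
    skew = float(np.mean((v - mu) ** 3) / m2**1.5)
    kurt = float(np.mean((v - mu) ** 4) / m2**2)  # non-excess
    ent = shannon_bits_16bit(v) if with_entropy16 else 0.0
    return HistogramSummary(mode=mode, sigma=sigma, skewness=skew, kurtosis=kurt, shannon_bits=ent)
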