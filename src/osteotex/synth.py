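"""Synthetic texture generator: fBm surfaces and lesion-like blob overlays.

A fractional-Brownian surface with Hurst exponent H is synthesized
spectrally (power spectrum proportional to f^-(2H+2)); its intensity
surface has fractal dimension 3 - H.  Sparse darkening Gaussian blobs
emulate the patchy radiolucency of trabecular bone loss, raising
lacunarity without changing the underlying roughness class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osteotex.errors import ParameterError
from osteotex.features import extract_features
from osteotex.image import GrayImage

_BLOB_R_MIN = 3.0
_BLOB_R_MAX = 8.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-class synthetic cohort."""

    n_per_class: int = 30
    image_size: int = 128
    h0: float = 0.7
    h1: float = 0.5
    blob_density: float = 0.02
    blob_contrast: float = 0.4
    noise_sigma: float = 0.0
    seed: int = 0
    fd_range: tuple[int, int] = (1, 4)
    ent_radii: tuple[int, int] = (1, 6)
    lac_sizes: tuple[int, int] = (3, 4)

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ParameterError("need at least 2 samples per class")
        for h in (self.h0, self.h1):
            if not (0.0 < h < 1.0):
                raise ParameterError("Hurst exponents must lie in (0, 1)")


def fbm_surface(size: int, H: float, seed: int) -> GrayImage:
    """Spectral-synthesis fractional-Brownian surface, min-max normalized."""
    if not (0.0 < H < 1.0):
        raise ParameterError("H must lie in (0, 1)")
    if size < 16 or size & (size - 1):
        raise ParameterError("size must be a power of 2, at least 16")
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(size)[None, :]
    fy = np.fft.fftfreq(size)[:, None]
    freq = np.sqrt(fx**2 + fy**2)
    amp = np.zeros_like(freq)
    nz = freq > 0
    amp[nz] = freq[nz] ** (-(H + 1.0))  # power ~ f^-(2H+2)
    noise = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
    surface = np.real(np.fft.ifft2(noise * amp))
    lo, hi = surface.min(), surface.max()
    pixels = (surface - lo) / (hi - lo) if hi > lo else np.zeros_like(surface)
    return GrayImage(pixels, meta={"H": H, "seed": seed})


def blob_texture(base: GrayImage, density: float, contrast: float, seed: int) -> GrayImage:
    """Superimpose sparse darkening Gaussian blobs (radius 3-8 px).

    The expected blob count is density * area / mean blob footprint
    (footprint = pi * E[r^2]); the realized count is stored in
    ``meta['n_blobs']``.
    """
    if not (0.0 <= density < 1.0):
        raise ParameterError("density must lie in [0, 1)")
    if contrast < 0:
        raise ParameterError("contrast must be nonnegative")
    pixels = base.pixels.copy()
    h, w = pixels.shape
    out = base.with_pixels(pixels)
    if density == 0.0 or contrast == 0.0:
        out.meta["n_blobs"] = 0
        return out
    rng = np.random.default_rng(seed)
    mean_r2 = (_BLOB_R_MAX**3 - _BLOB_R_MIN**3) / (3.0 * (_BLOB_R_MAX - _BLOB_R_MIN))
    mean_footprint = np.pi * mean_r2
    n_blobs = int(rng.poisson(density * h * w / mean_footprint))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(_BLOB_R_MIN, _BLOB_R_MAX)
        sd = r / 2.0
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        pixels -= contrast * np.exp(-d2 / (2.0 * sd * sd))
    out = base.with_pixels(np.clip(pixels, 0.0, 1.0))
    out.meta["n_blobs"] = n_blobs
    return out


def make_cohort(spec: CohortSpec) -> tuple[list[GrayImage], np.ndarray, pd.DataFrame]:
    """Two-class labeled image set with its 11-feature table.

    Class 0 is plain fBm(h0); class 1 is fBm(h1) plus blobs.  Fully
    deterministic under the master seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(4 * spec.n_per_class) % (2**31 - 1)
    images: list[GrayImage] = []
    labels = np.repeat([0, 1], spec.n_per_class)
    for k in range(spec.n_per_class):
        images.append(_noisy(fbm_surface(spec.image_size, spec.h0, int(seeds[k])), spec, int(seeds[2 * spec.n_per_class + k])))
    for k in range(spec.n_per_class):
        img = fbm_surface(spec.image_size, spec.h1, int(seeds[spec.n_per_class + k]))
        img = blob_texture(img, spec.blob_density, spec.blob_contrast, int(seeds[spec.n_per_class + k]) + 1)
        images.append(_noisy(img, spec, int(seeds[3 * spec.n_per_class + k])))
    rows = []
    for img, label in zip(images, labels):
        feats = extract_features(
            img,
            fd_range=spec.fd_range,
            ent_radii=spec.ent_radii,
            lac_sizes=spec.lac_sizes,
        )
        feats["label"] = int(label)
        rows.append(feats)
    table = pd.DataFrame(rows)
    return images, labels, table


def _noisy(img: GrayImage, spec: CohortSpec, seed: int) -> GrayImage:
    if spec.noise_sigma <= 0:
        return img
    rng = np.random.default_rng(seed)
    noisy = img.pixels + rng.normal(0.0, spec.noise_sigma, img.pixels.shape)
    out = img.with_pixels(np.clip(noisy, 0.0, 1.0))
    return out
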