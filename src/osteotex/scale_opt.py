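"""Davies-Bouldin scale selection for the three texture-feature families."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osteotex.errors import ConfigurationError, DataError, LabelError
from osteotex.fractal import ScaleSeries

FD_STAT_NAMES = ("mode", "sigma", "skewness", "kurtosis", "shannon_bits")
ENT_STAT_NAMES = ("mode", "sigma", "skewness", "kurtosis")


@dataclass
class DBIScore:
    """Davies-Bouldin index with its per-class ingredients."""

    value: float
    classes: int
    per_class_scatter: dict
    centroids: dict


@dataclass(frozen=True)
class CandidateGrid:
    """Candidate scale configurations to scan per feature family."""

    fd_ranges: tuple[tuple[int, int], ...] = ((1, 3), (1, 4), (1, 5), (1, 6), (1, 7))
    entropy_pairs: tuple[tuple[int, int], ...] = (
        (1, 4), (1, 5), (1, 6), (1, 7), (1, 8), (2, 5), (2, 6), (2, 7),
    )
    lac_sizes: tuple[int, ...] = (2, 3, 4, 5, 6, 7)

    def __post_init__(self) -> None:
        if not (self.fd_ranges and self.entropy_pairs and self.lac_sizes):
            raise ConfigurationError("candidate lists must be non-empty")


@dataclass
class SelectedScales:
    """Argmin-DBI configuration per feature family."""

    fd_range: tuple[int, int]
    entropy_pair: tuple[int, int]
    lac_sizes: tuple[int, int]
    report: pd.DataFrame = field(repr=False, default=None)


def davies_bouldin(points: np.ndarray, labels) -> DBIScore:
    """Davies-Bouldin index: mean over classes of the worst
    (scatter_k + scatter_l) / centroid-distance ratio.

    Scatter is the mean Euclidean distance of class members to their
    centroid.  Coincident centroids yield +inf.
    """
    x = np.asarray(points, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise DataError("feature matrix must be finite")
    y = np.asarray(labels)
    if y.shape[0] != x.shape[0]:
        raise DataError("labels length must match points")
    classes = np.unique(y)
    if classes.size < 2:
        raise LabelError("need at least 2 classes")
    centroids = {c: x[y == c].mean(axis=0) for c in classes}
    scatter = {
        c: float(np.linalg.norm(x[y == c] - centroids[c], axis=1).mean()) for c in classes
    }
    ratios = []
    for c in classes:
        worst = 0.0
        for other in classes:
            if other == c:
                continue
            gap = float(np.linalg.norm(centroids[c] - centroids[other]))
            worst = max(worst, np.inf if gap == 0 else (scatter[c] + scatter[other]) / gap)
        ratios.append(worst)
    return DBIScore(
        value=float(np.mean(ratios)),
        classes=int(classes.size),
        per_class_scatter=scatter,
        centroids=centroids,
    )


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def scan_scales(images, labels, grid: CandidateGrid, keep: float = 0.8) -> SelectedScales:
    """Exhaustive DBI scan over candidate scales for each feature family.

    ``images`` is a list of GrayImage (or 2-D arrays); ``labels`` the
    per-image class labels (two classes).  Per candidate, the family's
    per-image statistic vector is z-scored across samples and scored with
    the DBI; the argmin wins (two smallest for lacunarity box sizes).
    Candidates infeasible for the image size are skipped with a warning.
    """
    from osteotex.features import entropy_stats_vector, fd_stats_vector, lac_scalar

    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise LabelError("need at least 2 classes of images")

    rows = []

    def _score(family: str, name: str, extractor) -> float | None:
        vecs = []
        try:
            for img in images:
                vecs.append(extractor(img))
        except Exception as exc:  # infeasible candidate for this image size
            warnings.warn(f"skipping {family} candidate {name}: {exc}", stacklevel=3)
            return None
        mat = _zscore_columns(np.asarray(vecs, dtype=np.float64))
        if not np.all(np.isfinite(mat)):
            warnings.warn(f"skipping {family} candidate {name}: non-finite stats", stacklevel=3)
            return None
        dbi = davies_bouldin(mat, y).value
        rows.append({"family": family, "candidate": name, "dbi": dbi})
        return dbi

    fd_scores: dict[tuple[int, int], float] = {}
    for r_min, r_max in grid.fd_ranges:
        dbi = _score(
            "fd",
            f"{r_min}-{r_max}",
            lambda img, a=r_min, b=r_max: fd_stats_vector(img, ScaleSeries(a, b), keep=keep),
        )
        if dbi is not None:
            fd_scores[(r_min, r_max)] = dbi

    ent_scores: dict[tuple[int, int], float] = {}
    for r_meas, r_cnt in grid.entropy_pairs:
        dbi = _score(
            "entropy",
            f"{r_meas},{r_cnt}",
            lambda img, a=r_meas, b=r_cnt: entropy_stats_vector(img, a, b),
        )
        if dbi is not None:
            ent_scores[(r_meas, r_cnt)] = dbi

    lac_scores: dict[int, float] = {}
    for size in grid.lac_sizes:
        dbi = _score("lacunarity", f"{size}x{size}", lambda img, r=size: [lac_scalar(img, r)])
        if dbi is not None:
            lac_scores[size] = dbi

    if not fd_scores or not ent_scores or len(lac_scores) < 2:
        raise ConfigurationError("not enough feasible candidates in the grid")

    fd_best = min(fd_scores, key=fd_scores.get)
    ent_best = min(ent_scores, key=ent_scores.get)
    lac_sorted = sorted(lac_scores, key=lac_scores.get)
    lac_best = tuple(sorted(lac_sorted[:2]))
    return SelectedScales(
        fd_range=fd_best,
        entropy_pair=ent_best,
        lac_sizes=lac_best,  # type: ignore[arg-type]
        report=pd.DataFrame(rows),
    )
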