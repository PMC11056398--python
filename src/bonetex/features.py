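"""Intensity-histogram and GLCM texture features.

Each trabecular ROI is summarized by a fixed, ordered 45-element vector:

* 5 histogram features of the raw HU values — mean, standard deviation,
  skewness, kurtosis and Shannon entropy;
* 40 GLCM features — the image is quantized to N gray levels for
  N in {16, 32, 64, 128}, a co-occurrence matrix is built for the
  horizontal (offset (0, +1)) and vertical (offset (+1, 0)) directions,
  and five Haralick-style statistics (entropy, contrast, correlation,
  homogeneity, variance) are taken from each of the 8 matrices.

Conventions (all unit-tested):

* Moments are population moments (divisor n); kurtosis is the non-excess
  Pearson form m4/m2^2.
* Histogram entropy uses 256 equal-width bins over the ROI's own range,
  log base 2.
* Quantization is per-ROI min-max equal-width by default; a fixed-HU-window
  mode is available because min-max binning discards the absolute HU scale.
* GLCMs are accumulated symmetrically (each pair increments (i, j) and
  (j, i)) and normalized to total mass 1.
* Degenerate inputs (constant ROI) yield finite values by convention:
  skewness = kurtosis = entropy = 0; GLCM correlation 0 when a marginal
  standard deviation vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .imaging import SliceImage
from .roi import DegenerateInputError

__all__ = [
    "Direction",
    "QuantizedImage",
    "Glcm",
    "FeatureVector",
    "FeatureConfig",
    "HISTOGRAM_FEATURE_NAMES",
    "GLCM_STATISTIC_NAMES",
    "feature_names",
    "histogram_features",
    "quantize",
    "glcm",
    "glcm_statistics",
    "extract_features",
]

DEFAULT_LEVELS = (16, 32, 64, 128)
HISTOGRAM_FEATURE_NAMES = ("hist_mean", "hist_std", "hist_skew", "hist_kurt", "hist_entropy")
GLCM_STATISTIC_NAMES = ("entropy", "contrast", "correlation", "homogeneity", "variance")
_HIST_ENTROPY_BINS = 256


class Direction(str, Enum):
    """Pixel-pair offset direction: horizontal is (0, +1), vertical (+1, 0)."""

    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"

    @property
    def offset(self) -> tuple[int, int]:
        return (0, 1) if self is Direction.HORIZONTAL else (1, 0)


@dataclass
class QuantizedImage:
    """ROI reduced to integer gray levels in [0, n_levels - 1]."""

    levels: np.ndarray
    n_levels: int
    hu_min: float
    hu_max: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.min(initial=0) < 0 or self.levels.max(initial=0) >= self.n_levels:
            raise ValueError("quantized levels out of [0, n_levels - 1]")


@dataclass
class Glcm:
    """Normalized gray-level co-occurrence matrix for one (N, direction)."""

    P: np.ndarray
    n_levels: int
    direction: Direction
    pair_count: int

    def __post_init__(self) -> None:
        if self.P.shape != (self.n_levels, self.n_levels):
            raise ValueError(f"P must be {self.n_levels}x{self.n_levels}")
        if self.pair_count <= 0:
            raise ValueError("pair_count must be positive")


@dataclass
class FeatureVector:
    """Ordered, named 45-element feature vector for one ROI."""

    values: np.ndarray
    names: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class FeatureConfig:
    """Options for :func:`extract_features`.

    ``quantize_mode`` is "minmax" (per-ROI range) or "fixed" (the HU window
    ``fixed_hu_low``..``fixed_hu_high``); ``homogeneity_kind`` selects the
    1/(1+(i-j)^2) inverse-difference-moment form ("squared", default) or the
    1/(1+|i-j|) variant ("abs").
    """

    levels: tuple[int, ...] = DEFAULT_LEVELS
    directions: tuple[Direction, ...] = (Direction.HORIZONTAL, Direction.VERTICAL)
    symmetric: bool = True
    homogeneity_kind: str = "squared"
    quantize_mode: str = "minmax"
    fixed_hu_low: float = 0.0
    fixed_hu_high: float = 400.0

    def __post_init__(self) -> None:
        self.levels = tuple(sorted(int(n) for n in self.levels))
        if not self.levels or any(n < 2 for n in self.levels):
            raise ValueError("levels must be a non-empty set of integers >= 2")
        self.directions = tuple(Direction(d) for d in self.directions)
        if self.quantize_mode not in ("minmax", "fixed"):
            raise ValueError(f"unknown quantize_mode {self.quantize_mode!r}")
        if self.homogeneity_kind not in ("squared", "abs"):
            raise ValueError(f"unknown homogeneity_kind {self.homogeneity_kind!r}")


def feature_names(config: FeatureConfig | None = None) -> tuple[str, ...]:
    """The fixed feature-name order: 5 histogram names, then
    ``glcm_{N}_{direction}_{statistic}`` for N ascending, horizontal before
    vertical, statistics in (entropy, contrast, correlation, homogeneity,
    variance)."""
    config = config or FeatureConfig()
    names = list(HISTOGRAM_FEATURE_NAMES)
    for n in config.levels:
        for direction in config.directions:
            for stat in GLCM_STATISTIC_NAMES:
                names.append(f"glcm_{n}_{direction.value}_{stat}")
    return tuple(names)


def histogram_features(roi: SliceImage) -> dict[str, float]:
    """First-order statistics of the ROI's HU histogram.

    mean and population std; skewness m3/m2^1.5 and Pearson kurtosis
    m4/m2^2; Shannon entropy (bits) of a 256-bin equal-width histogram over
    [min, max].  A constant ROI yields (c, 0, 0, 0, 0) by convention.
    """
    x = roi.pixels.ravel()
    if x.size < 4:
        raise DegenerateInputError(f"ROI has {x.size} pixels; need >= 4")
    mean = float(x.mean())
    centered = x - mean
    m2 = float(np.mean(centered**2))
    std = math.sqrt(m2)
    if m2 == 0.0:
        return dict(zip(HISTOGRAM_FEATURE_NAMES, (mean, 0.0, 0.0, 0.0, 0.0)))
    skew = float(np.mean(centered**3)) / m2**1.5
    kurt = float(np.mean(centered**4)) / m2**2
    counts, _ = np.histogram(x, bins=_HIST_ENTROPY_BINS, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    return dict(zip(HISTOGRAM_FEATURE_NAMES, (mean, std, skew, kurt, entropy)))


def quantize(
    roi: SliceImage,
    n_levels: int,
    hu_range: tuple[float, float] | None = None,
) -> QuantizedImage:
    """Reduce HU values to ``n_levels`` equal-width bins.

    level = floor(N * (x - min) / (max - min)), clamped to N - 1.  With
    ``hu_range`` given, values are first clipped to that fixed window
    instead of using the ROI's own min/max; a constant ROI maps to all
    zeros.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    x = roi.pixels
    if hu_range is None:
        lo, hi = float(x.min()), float(x.max())
    else:
        lo, hi = map(float, hu_range)
        if not lo < hi:
            raise ValueError(f"invalid HU range [{lo}, {hi}]")
        x = np.clip(x, lo, hi)
    if lo == hi:
        return QuantizedImage(np.zeros_like(x, dtype=np.int64), n_levels, lo, hi)
    levels = np.floor(n_levels * (x - lo) / (hi - lo)).astype(np.int64)
    np.clip(levels, 0, n_levels - 1, out=levels)
    return QuantizedImage(levels, n_levels, lo, hi)


def glcm(q: QuantizedImage, direction: Direction | str, symmetric: bool = True) -> Glcm:
    """Co-occurrence probability matrix at the direction's unit offset.

    Each pixel pair increments (i, j) and — in the default symmetric mode —
    also (j, i); the matrix is normalized by the total number of increments
    so it sums to 1.
    """
    direction = Direction(direction)
    dr, dc = direction.offset
    lv = q.levels
    n_rows, n_cols = lv.shape
    if n_rows - dr < 1 or n_cols - dc < 1:
        raise DegenerateInputError(
            f"image of shape {lv.shape} has no pixel pair in direction {direction.value}"
        )
    a = lv[: n_rows - dr, : n_cols - dc].ravel()
    b = lv[dr:, dc:].ravel()
    n = q.n_levels
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n).astype(float)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return Glcm(counts / total, n, direction, pair_count=a.size)


def glcm_statistics(g: Glcm, homogeneity_kind: str = "squared") -> dict[str, float]:
    """Five Haralick-style statistics of a GLCM.

    entropy = -sum P log2 P (0 log 0 = 0); contrast = sum (i-j)^2 P;
    correlation uses the marginal means/stds (0 by convention when a
    marginal std vanishes); homogeneity = sum P / (1 + (i-j)^2) (or
    1 + |i-j| for ``homogeneity_kind="abs"``); variance is the Haralick
    sum-of-squares on the row marginal, sum (i - mu_i)^2 P.
    """
    P = g.P
    n = g.n_levels
    idx = np.arange(n, dtype=float)
    i = idx[:, None]
    j = idx[None, :]

    pos = P[P > 0]
    entropy = float(-(pos * np.log2(pos)).sum())
    contrast = float(((i - j) ** 2 * P).sum())

    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = float(idx @ p_i)
    mu_j = float(idx @ p_j)
    var_i = float(((idx - mu_i) ** 2) @ p_i)
    var_j = float(((idx - mu_j) ** 2) @ p_j)
    if var_i == 0.0 or var_j == 0.0:
        correlation = 0.0
    else:
        cov = float(((i - mu_i) * (j - mu_j) * P).sum())
        correlation = cov / math.sqrt(var_i * var_j)

    if homogeneity_kind == "squared":
        homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    elif homogeneity_kind == "abs":
        homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    else:
        raise ValueError(f"unknown homogeneity_kind {homogeneity_kind!r}")

    variance = float(((i - mu_i) ** 2 * P).sum())
    return dict(
        zip(
            GLCM_STATISTIC_NAMES,
            (entropy, contrast, correlation, homogeneity, variance),
        )
    )


def extract_features(roi: SliceImage, config: FeatureConfig | None = None) -> FeatureVector:
    """The full 45-feature vector: 5 histogram features followed by the 5
    GLCM statistics for every (N, direction) in the configured order."""
    config = config or FeatureConfig()
    values = list(histogram_features(roi).values())
    hu_range = (
        (config.fixed_hu_low, config.fixed_hu_high)
        if config.quantize_mode == "fixed"
        else None
    )
    for n in config.levels:
        q = quantize(roi, n, hu_range=hu_range)
        for direction in config.directions:
            try:
                g = glcm(q, direction, symmetric=config.symmetric)
                stats = glcm_statistics(g, homogeneity_kind=config.homogeneity_kind)
            except Exception as exc:
                raise type(exc)(f"(N={n}, direction={direction.value}) {exc}") from exc
            values.extend(stats.values())
    return FeatureVector(np.array(values), feature_names(config), source_id=roi.source_id)
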