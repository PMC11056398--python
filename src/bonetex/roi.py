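"""Trabecular ROI isolation.

The trabecular compartment is isolated by HU-window thresholding; the
analysis region is the maximum-area axis-aligned rectangle inscribed in the
largest connected component of the thresholded mask.  This gives a
deterministic, parameter-free operationalization of a rectangle "covering
most of the trabecular area".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import SliceImage

__all__ = [
    "RoiRegion",
    "DegenerateInputError",
    "threshold_mask",
    "largest_component",
    "inscribed_rectangle",
    "extract_roi",
    "find_trabecular_roi",
]

DEFAULT_HU_LOW = 0.0
DEFAULT_HU_HIGH = 400.0
DEFAULT_MIN_ROI_AREA = 64


class DegenerateInputError(ValueError):
    """Raised when an image or mask cannot support ROI placement."""


@dataclass
class RoiRegion:
    """An axis-aligned rectangle in 0-based half-open pixel coordinates,
    together with the binary mask it was inscribed in."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end <= self.mask.shape[0]):
            raise ValueError(f"row bounds invalid: {self}")
        if not (0 <= self.col_start < self.col_end <= self.mask.shape[1]):
            raise ValueError(f"col bounds invalid: {self}")
        if not bool(
            self.mask[self.row_start : self.row_end, self.col_start : self.col_end].all()
        ):
            raise ValueError("rectangle contains pixels outside the mask")

    @property
    def area(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)


def threshold_mask(img: SliceImage, hu_low: float, hu_high: float) -> np.ndarray:
    """Boolean mask of pixels with hu_low <= HU <= hu_high (inclusive).

    No morphology is applied here.  Raises :class:`DegenerateInputError`
    if no pixel falls inside the window.
    """
    if not hu_low < hu_high:
        raise ValueError(f"hu_low must be < hu_high, got [{hu_low}, {hu_high}]")
    mask = (img.pixels >= hu_low) & (img.pixels <= hu_high)
    if not mask.any():
        raise DegenerateInputError(
            f"no pixels in HU window [{hu_low}, {hu_high}] for {img.source_id!r}"
        )
    return mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 4-connected component of a boolean mask.

    Size ties are broken by the component whose first pixel in row-major
    scan order comes first.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    # scipy labels components in scan order of their first pixel, so the first
    # argmax is also the scan-order tie-break.
    best = int(np.argmax(sizes)) + 1
    return labels == best


def inscribed_rectangle(
    mask: np.ndarray, min_roi_area: int = DEFAULT_MIN_ROI_AREA, source_id: str = ""
) -> RoiRegion:
    """Maximum-area axis-aligned rectangle of all-true pixels in a mask.

    Uses the histogram-of-heights stack algorithm: for each row, the height
    profile of consecutive true pixels ending at that row is built, and the
    largest rectangle under that histogram is found in O(cols) with a
    monotonic stack — O(rows x cols) overall.

    Ties are broken by larger row-extent, then smaller ``row_start``, then
    smaller ``col_start``.
    """
    mask = np.asarray(mask, dtype=bool)
    n_rows, n_cols = mask.shape
    heights = np.zeros(n_cols, dtype=int)
    # best = (area, row_extent, -row_start, -col_start) maximized lexically
    best_key: tuple[int, int, int, int] | None = None
    best_rect: tuple[int, int, int, int] | None = None

    for r in range(n_rows):
        heights = np.where(mask[r], heights + 1, 0)
        stack: list[int] = []  # column indices with increasing heights
        for c in range(n_cols + 1):
            h = heights[c] if c < n_cols else 0
            while stack and heights[stack[-1]] >= h:
                top = stack.pop()
                height = int(heights[top])
                left = stack[-1] + 1 if stack else 0
                width = c - left
                area = height * width
                rect = (r + 1 - height, r + 1, left, c)
                key = (area, height, -rect[0], -rect[2])
                if best_key is None or key > best_key:
                    best_key, best_rect = key, rect
            stack.append(c)

    if best_rect is None or best_key is None or best_key[0] < min_roi_area:
        got = 0 if best_key is None else best_key[0]
        raise DegenerateInputError(
            f"no inscribed rectangle of area >= {min_roi_area} (best {got})"
        )
    r0, r1, c0, c1 = best_rect
    return RoiRegion(r0, r1, c0, c1, mask=mask, source_id=source_id)


def extract_roi(img: SliceImage, region: RoiRegion) -> SliceImage:
    """Crop the image to the region's rectangle; spacing and metadata
    propagate unchanged."""
    n_rows, n_cols = img.shape
    if region.row_end > n_rows or region.col_end > n_cols:
        raise IndexError(
            f"region {region.row_start}:{region.row_end}, "
            f"{region.col_start}:{region.col_end} exceeds image shape {img.shape}"
        )
    sub = img.pixels[region.row_start : region.row_end, region.col_start : region.col_end]
    return SliceImage(
        sub.copy(),
        img.pixel_spacing_mm,
        source_id=img.source_id,
        metadata=dict(img.metadata),
    )


def find_trabecular_roi(
    img: SliceImage,
    hu_low: float = DEFAULT_HU_LOW,
    hu_high: float = DEFAULT_HU_HIGH,
    closing: bool = True,
    min_roi_area: int = DEFAULT_MIN_ROI_AREA,
) -> RoiRegion:
    """Full ROI pipeline: threshold, optional 3x3 morphological closing to
    bridge thin trabecular gaps, largest component, inscribed rectangle."""
    mask = threshold_mask(img, hu_low, hu_high)
    if closing:
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
        if not mask.any():
            raise DegenerateInputError("mask empty after morphological closing")
    component = largest_component(mask)
    return inscribed_rectangle(component, min_roi_area=min_roi_area, source_id=img.source_id)
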