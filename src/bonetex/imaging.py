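"""CT slice input/output.

Reads single-frame CT DICOM files and a plain-text matrix fixture format,
always converting stored pixel values to Hounsfield units (HU).  The rest of
the package works exclusively on :class:`SliceImage` objects, so everything
scanner-specific stops here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SliceImage",
    "FixtureFormatError",
    "DicomFormatError",
    "read_dicom_slice",
    "read_matrix_fixture",
    "write_matrix_fixture",
]

logger = logging.getLogger(__name__)

# HU values far outside this range suggest a unit or rescale problem; they are
# reported but never rejected, because the downstream math is unit-agnostic.
_PLAUSIBLE_HU = (-2000.0, 5000.0)


class FixtureFormatError(ValueError):
    """Raised when a text matrix fixture is malformed."""


class DicomFormatError(ValueError):
    """Raised when a DICOM file is not a usable single-frame image."""


@dataclass
class SliceImage:
    """A 2D axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels
        2D float array of HU values, shape (rows, cols), both >= 2.
    pixel_spacing_mm
        (row spacing, column spacing) in millimetres, both positive.
    source_id
        Opaque identifier (typically the originating file name).
    metadata
        Pass-through acquisition metadata (kVp, slice thickness, ...);
        never interpreted by the analysis.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    source_id: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 2:
            raise ValueError(f"both image dimensions must be >= 2, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite HU values")
        rs, cs = self.pixel_spacing_mm
        if rs <= 0 or cs <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing_mm}")
        self.pixel_spacing_mm = (float(rs), float(cs))
        lo, hi = _PLAUSIBLE_HU
        if self.pixels.min() < lo or self.pixels.max() > hi:
            warnings.warn(
                f"HU values outside plausible range [{lo}, {hi}] in {self.source_id!r}",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_dicom_slice(path: str | Path) -> SliceImage:
    """Read a single-frame CT DICOM file and rescale to HU.

    HU = stored_value * RescaleSlope + RescaleIntercept.  Missing slope or
    intercept default to 1 and 0 with a logged warning; all other elements are
    carried as string metadata only.

    Raises
    ------
    OSError
        If the file cannot be read.
    DicomFormatError
        For multi-frame objects or files without pixel data.
    """
    import pydicom

    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except OSError:
        raise
    except Exception as exc:  # pydicom raises its own parse errors
        raise DicomFormatError(f"not a readable DICOM file: {path}: {exc}") from exc

    if "PixelData" not in ds:
        raise DicomFormatError(f"no pixel data in {path}")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise DicomFormatError(f"multi-frame object not supported: {path}")

    stored = ds.pixel_array
    if stored.ndim != 2:
        raise DicomFormatError(f"expected a 2D frame, got shape {stored.shape} in {path}")

    slope = getattr(ds, "RescaleSlope", None)
    intercept = getattr(ds, "RescaleIntercept", None)
    if slope is None or intercept is None:
        logger.warning("missing RescaleSlope/Intercept in %s; assuming slope=1, intercept=0", path)
        slope = 1.0 if slope is None else slope
        intercept = 0.0 if intercept is None else intercept
    hu = stored.astype(float) * float(slope) + float(intercept)

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        logger.warning("missing PixelSpacing in %s; assuming 1.0 mm", path)
        spacing_mm = (1.0, 1.0)
    else:
        spacing_mm = (float(spacing[0]), float(spacing[1]))

    meta = {}
    for keyword in ("KVP", "SliceThickness", "ConvolutionKernel", "Manufacturer",
                    "ManufacturerModelName", "StudyDate", "Modality"):
        value = getattr(ds, keyword, None)
        if value is not None:
            meta[keyword] = str(value)

    return SliceImage(hu, spacing_mm, source_id=path.name, metadata=meta)


def read_matrix_fixture(path: str | Path) -> SliceImage:
    """Read a plain-text HU matrix: one image row per line, optional header.

    The optional first line ``# spacing <row_mm> <col_mm>`` sets the pixel
    spacing; it defaults to (1.0, 1.0).  Values are whitespace- or
    comma-delimited and taken verbatim as HU.
    """
    path = Path(path)
    spacing = (1.0, 1.0)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").split()
                if parts[:1] == ["spacing"]:
                    if len(parts) != 3:
                        raise FixtureFormatError(f"{path}:{lineno}: malformed spacing header")
                    spacing = (float(parts[1]), float(parts[2]))
                continue
            tokens = line.replace(",", " ").split()
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise FixtureFormatError(f"{path}:{lineno}: non-numeric token") from exc
    if not rows:
        raise FixtureFormatError(f"{path}: empty fixture")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FixtureFormatError(f"{path}: ragged rows")
    return SliceImage(np.array(rows, dtype=float), spacing, source_id=path.name)


def write_matrix_fixture(img: SliceImage, path: str | Path, sig_digits: int = 6) -> None:
    """Write a SliceImage in the text fixture format read by
    :func:`read_matrix_fixture`.

    Floats are serialized with ``sig_digits`` significant digits (default 6),
    so round-trips are exact to ~1e-5 relative tolerance.
    """
    path = Path(path)
    fmt = f"%.{sig_digits}g"
    with open(path, "w") as fh:
        rs, cs = img.pixel_spacing_mm
        fh.write(f"# spacing {fmt % rs} {fmt % cs}\n")
        for row in img.pixels:
            fh.write(" ".join(fmt % v for v in row) + "\n")
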