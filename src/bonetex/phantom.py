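"""Synthetic trabecular phantom cohort.

A test instrument, not an anatomical model: each slice is an elliptical
"vertebral body" with a dense cortical rim and a two-phase trabecular
interior, embedded in a soft-tissue background.  The interior texture is a
smoothed Gaussian random field thresholded at the (1 - d) quantile, so a
latent density parameter d in [0, 1] directly controls both the bone-pixel
fraction (hence mean HU) and, via the field's correlation length, the
texture coarseness the GLCM features respond to.  Reference BMD values are
an affine function of the case-mean density plus optional Gaussian noise,
standing in for a DXA measurement.

Default HU palette: background -50 (fatty soft tissue), marrow 100,
trabecular bone 300, cortical rim bone + 400 = 700, additive noise 5 HU.
The palette is chosen so the interior (marrow and bone alike) falls inside
the default trabecular threshold window [0, 400] while background and rim
fall outside it, and so the interior mean HU spans the clinically typical
trabecular range of roughly 100-300 HU as d goes 0 to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import SliceImage, write_matrix_fixture

__all__ = [
    "PhantomSpec",
    "SyntheticCohortSpec",
    "generate_phantom",
    "generate_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = (
    "case_id",
    "patient_id",
    "vertebra_level",
    "image_path",
    "lumbar_total",
    "lumbar_total_excl_L1",
    "hip_total",
    "true_density",
)


@dataclass
class PhantomSpec:
    """Geometry, HU palette and texture parameters for one slice."""

    image_size: tuple[int, int] = (128, 128)
    semi_axes: tuple[float, float] = (48.0, 38.0)  # (row, col) semi-axes, px
    rim_thickness: float = 3.0  # cortical shell, px
    density: float = 0.5  # latent trabecular density d in [0, 1]
    marrow_hu: float = 100.0
    bone_hu: float = 300.0
    background_hu: float = -50.0
    correlation_length: float = 2.5  # Gaussian-field smoothing sigma, px
    noise_sd: float = 5.0  # additive HU noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        if self.correlation_length < 1.0:
            raise ValueError("correlation length must be >= 1 pixel")
        n_rows, n_cols = self.image_size
        a, b = self.semi_axes
        if a + 1 > n_rows / 2 or b + 1 > n_cols / 2:
            raise ValueError("body ellipse (with rim) does not fit inside the image")
        if min(a, b) - self.rim_thickness < 4:
            raise ValueError("interior too small after removing the cortical rim")


@dataclass
class SyntheticCohortSpec:
    """Cohort-level parameters.

    One latent density is drawn per case (uniform over ``density_range``);
    each vertebral level gets that density plus a small within-case jitter,
    mirroring the modest inter-vertebral variation of real spines.  The
    lumbar reference is ``bmd = link_a + link_b * mean(d)`` over the case's
    levels; the hip reference uses coefficients (0.9 a, 0.85 b) to emulate
    an imperfectly matched second site.  Gaussian noise ``bmd_noise_sd``
    (g/cm^2) is added to both references.
    """

    n_cases: int = 200
    levels: tuple[str, ...] = ("L1", "L2", "L3")
    link_a: float = 0.6  # g/cm^2 at d = 0
    link_b: float = 0.6  # g/cm^2 per unit density
    bmd_noise_sd: float = 0.0
    density_range: tuple[float, float] = (0.05, 0.95)
    level_jitter_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.link_b == 0:
            raise ValueError("link_b must be non-zero")
        lo, hi = self.density_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("density_range must be within [0, 1] with lo < hi")


def _ellipse_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(body, interior) boolean masks; interior excludes the cortical rim."""
    n_rows, n_cols = spec.image_size
    r = np.arange(n_rows)[:, None] - (n_rows - 1) / 2.0
    c = np.arange(n_cols)[None, :] - (n_cols - 1) / 2.0
    a, b = spec.semi_axes
    t = spec.rim_thickness
    body = (r / a) ** 2 + (c / b) ** 2 <= 1.0
    interior = (r / (a - t)) ** 2 + (c / (b - t)) ** 2 <= 1.0
    return body, interior


def generate_phantom(spec: PhantomSpec) -> SliceImage:
    """Render one synthetic axial slice, fully determined by the seed.

    The trabecular lattice marks interior pixels as bone where a smoothed
    unit Gaussian field exceeds its interior (1 - d) quantile, so the
    bone-pixel fraction is d up to quantile granularity; independent
    Gaussian HU noise is added everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    body, interior = _ellipse_masks(spec)

    field_ = ndimage.gaussian_filter(
        rng.standard_normal(spec.image_size), sigma=spec.correlation_length
    )
    interior_vals = field_[interior]
    if spec.density >= 1.0:
        bone = interior
    elif spec.density <= 0.0:
        bone = np.zeros_like(interior)
    else:
        threshold = np.quantile(interior_vals, 1.0 - spec.density)
        bone = interior & (field_ > threshold)

    hu = np.full(spec.image_size, spec.background_hu)
    hu[body] = spec.bone_hu + 400.0  # cortical rim
    hu[interior] = spec.marrow_hu
    hu[bone] = spec.bone_hu
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.image_size)
    return SliceImage(hu, source_id=f"phantom_seed{spec.seed}")


def generate_cohort(
    spec: SyntheticCohortSpec,
    out_dir: str | Path,
    phantom_template: PhantomSpec | None = None,
) -> tuple[Path, pd.DataFrame]:
    """Write a synthetic cohort (text-matrix slices + cohort CSV) to disk.

    Returns the CSV path and the cohort table.  All randomness is derived
    from ``spec.seed`` through independent child streams (densities, slice
    rendering, BMD noise), so the same seed reproduces the cohort
    byte-for-byte and changing ``bmd_noise_sd`` leaves the slices untouched.
    """
    template = phantom_template or PhantomSpec()
    out_dir = Path(out_dir)
    slices_dir = out_dir / "slices"
    slices_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(spec.seed)
    density_ss, slice_ss, bmd_ss = root.spawn(3)
    density_rng = np.random.default_rng(density_ss)
    bmd_rng = np.random.default_rng(bmd_ss)
    slice_seeds = slice_ss.generate_state(spec.n_cases * len(spec.levels)) % (2**31)

    lo, hi = spec.density_range
    rows = []
    k = 0
    for i in range(spec.n_cases):
        case_id = f"C{i:04d}"
        patient_id = f"P{i:04d}"
        d_case = density_rng.uniform(lo, hi)
        level_d = np.clip(
            d_case + density_rng.normal(0.0, spec.level_jitter_sd, size=len(spec.levels)),
            0.0,
            1.0,
        )
        mean_d = float(level_d.mean())
        non_l1 = [d for lvl, d in zip(spec.levels, level_d) if lvl != "L1"]
        mean_d_excl = float(np.mean(non_l1)) if non_l1 else np.nan

        noise_lumbar = bmd_rng.normal() * spec.bmd_noise_sd
        noise_hip = bmd_rng.normal() * spec.bmd_noise_sd
        lumbar = spec.link_a + spec.link_b * mean_d + noise_lumbar
        lumbar_excl = (
            spec.link_a + spec.link_b * mean_d_excl + noise_lumbar
            if np.isfinite(mean_d_excl)
            else np.nan
        )
        hip = 0.9 * spec.link_a + 0.85 * spec.link_b * mean_d + noise_hip

        for level, d in zip(spec.levels, level_d):
            slice_spec = replace(template, density=float(d), seed=int(slice_seeds[k]))
            k += 1
            img = generate_phantom(slice_spec)
            img_path = slices_dir / f"{case_id}_{level}.txt"
            write_matrix_fixture(img, img_path)
            # stored relative to the CSV so the cohort is relocatable and
            # byte-identical across output directories
            rows.append(
                {
                    "case_id": case_id,
                    "patient_id": patient_id,
                    "vertebra_level": level,
                    "image_path": f"slices/{img_path.name}",
                    "lumbar_total": lumbar,
                    "lumbar_total_excl_L1": lumbar_excl,
                    "hip_total": hip,
                    "true_density": float(d),
                }
            )

    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    csv_path = out_dir / "cohort.csv"
    table.to_csv(csv_path, index=False, float_format="%.6f")
    table = table.assign(image_path=[str(out_dir / p) for p in table["image_path"]])
    return csv_path, table
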