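"""Digital-phantom cohort generator for PET lymph-node volumetry.

Each phantom case emulates one patient image around a single PSMA-avid
lymph-node lesion: an ellipsoidal lesion of homogeneous uptake embedded in
soft tissue, three spatially separated background-tissue blocks (liver,
parotid gland, spleen) with independently drawn SUVmean values, Gaussian
post-reconstruction smoothing and additive truncated-Gaussian noise.  The
analytic ellipsoid volume plays the role of the morphological (CT-derived)
reference volume, which is exactly known by construction.

Study-like cohort structure:

* lesion volumes are log-normal with median 3.2 ml, resampled into the
  observed range [1.0, 23.8] ml;
* lesion short-axis radius is kept >= 5 mm (short-axis diameter >= 10 mm);
* background SUVmean per tissue is log-normal, parameterized so the median
  matches the reported cohort medians (parotid 20.1, liver 11.3, spleen 9.9)
  and the 2.5-97.5 percentile span approximates the reported ranges; tissues
  are sampled independently, matching the reported absence of inter-tissue
  correlation;
* smoothing uses a 2 mm FWHM Gaussian kernel.

Randomness is reproducible case-by-case: each case draws from a dedicated
substream spawned from the cohort seed and the case index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .image_model import (
    BoxROI,
    DiscROI,
    EllipsoidVOI,
    GeometryError,
    ScalarVolume,
    rasterize,
)

__all__ = [
    "LogNormalSUV",
    "BackgroundModel",
    "LesionSpec",
    "PhantomLayout",
    "PhantomCase",
    "CohortConfig",
    "DEFAULT_LAYOUT",
    "ellipsoid_volume_ml",
    "sample_background_suvs",
    "generate_case",
    "generate_cohort",
    "cohort_truth_table",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def ellipsoid_volume_ml(semi_axes: tuple[float, float, float]) -> float:
    """Analytic ellipsoid volume (4/3)*pi*a*b*c in ml for semi-axes in mm."""
    a, b, c = semi_axes
    if min(a, b, c) <= 0:
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    return (4.0 / 3.0) * math.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class LogNormalSUV:
    """Log-normal SUVmean distribution stated by its median and range.

    ``sigma`` of the underlying normal is chosen so the 2.5-97.5 percentile
    interval spans ``(range_low, range_high)``; a degenerate range (low ==
    high) collapses to a point mass at the median.
    """

    median: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if not (0 < self.range_low <= self.median <= self.range_high):
            raise ValueError(
                f"need 0 < low <= median <= high, got "
                f"({self.range_low}, {self.median}, {self.range_high})"
            )

    @property
    def sigma(self) -> float:
        return math.log(self.range_high / self.range_low) / (2.0 * 1.959963985)

    def sample(self, rng: np.random.Generator, size=None):
        if self.sigma == 0.0:  # point mass: return the median exactly
            return self.median if size is None else np.full(size, self.median)
        return rng.lognormal(mean=math.log(self.median), sigma=self.sigma, size=size)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-tissue SUVmean distributions plus the image degradation model."""

    tissues: Mapping[str, LogNormalSUV] = field(
        default_factory=lambda: {
            "parotis": LogNormalSUV(20.1, 5.8, 36.3),
            "liver": LogNormalSUV(11.3, 4.2, 25.5),
            "spleen": LogNormalSUV(9.9, 4.7, 28.7),
            "soft_tissue": LogNormalSUV(1.0, 0.6, 1.7),
        }
    )
    noise_sd: float = 0.3
    psf_fwhm_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: position, semi-axes (mm) and pre-blur peak SUV."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    peak_suv: float

    def __post_init__(self) -> None:
        if min(self.semi_axes) < 5.0:
            raise ValueError(
                f"lesion short-axis radius must be >= 5 mm "
                f"(short-axis diameter >= 10 mm), got semi-axes {self.semi_axes}"
            )
        if self.peak_suv <= 0:
            raise ValueError("peak_suv must be positive")

    @property
    def volume_ml(self) -> float:
        return ellipsoid_volume_ml(self.semi_axes)


@dataclass(frozen=True)
class PhantomLayout:
    """World-space layout of the phantom: image extent, lesion site, tissue blocks.

    Background blocks are painted regions that carry the reference ROIs; they
    are placed far enough from the lesion site that the 2 mm PSF cannot mix
    lesion and background signal.
    """

    extent_mm: tuple[float, float, float] = (160.0, 160.0, 80.0)
    lesion_center: tuple[float, float, float] = (50.0, 50.0, 40.0)
    blocks: Mapping[str, BoxROI] = field(
        default_factory=lambda: {
            "liver": BoxROI.cube((120.0, 40.0, 40.0), 44.0),
            "parotis": BoxROI.cube((120.0, 110.0, 40.0), 20.0),
            "spleen": BoxROI.cube((50.0, 120.0, 40.0), 44.0),
        }
    )

    def rois(self) -> dict[str, BoxROI | DiscROI]:
        """Reference ROIs: 30 mm axial disc (liver), 10 mm cube (parotid),
        30 mm cube (spleen), centered in their tissue blocks."""
        return {
            "liver": DiscROI(self.blocks["liver"].center, 30.0),
            "parotis": BoxROI.cube(self.blocks["parotis"].center, 10.0),
            "spleen": BoxROI.cube(self.blocks["spleen"].center, 30.0),
        }

    def grid_shape(self, spacing: float) -> tuple[int, int, int]:
        return tuple(int(round(e / spacing)) for e in self.extent_mm)  # type: ignore[return-value]


DEFAULT_LAYOUT = PhantomLayout()


@dataclass(frozen=True)
class PhantomCase:
    """One simulated lesion with everything delineation and evaluation need."""

    case_id: str
    pet: ScalarVolume
    voi: EllipsoidVOI
    ct_reference_volume_ml: float
    background_suvs: dict[str, float]
    rois: dict[str, BoxROI | DiscROI]
    lesion: LesionSpec


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions for a phantom cohort.

    Defaults reproduce the study conditions: 50 lesions with volumes in
    [1.0, 23.8] ml (median 3.2 ml), lesion peak SUV uniform in [8, 40],
    2 mm FWHM smoothing and 0.3 SUV noise (via ``background``).
    """

    n_cases: int = 50
    volume_median_ml: float = 3.2
    volume_log_sd: float = 0.6
    volume_range_ml: tuple[float, float] = (1.0, 23.8)
    aspect_range: tuple[float, float] = (1.0, 1.6)
    peak_suv_range: tuple[float, float] = (8.0, 40.0)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    spacing_mm: float = 2.0
    voi_margin_mm: float = 6.0
    layout: PhantomLayout = field(default_factory=PhantomLayout)
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        lo, hi = self.volume_range_ml
        if not (0 < lo < hi):
            raise ValueError("volume range must satisfy 0 < low < high")


def sample_background_suvs(
    model: BackgroundModel,
    rng: np.random.Generator | int,
    size: int | None = None,
) -> dict[str, float] | dict[str, np.ndarray]:
    """Draw SUVmean truth values, one per tissue, independently across tissues.

    With ``size`` given, returns arrays of draws per tissue (for calibration
    checks); otherwise scalar floats.  Reproducible for a fixed seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: dict = {}
    for name in sorted(model.tissues):
        draw = model.tissues[name].sample(rng, size=size)
        out[name] = float(draw) if size is None else np.asarray(draw)
    return out


def _check_lesion_fits(
    lesion: LesionSpec, layout: PhantomLayout, model: BackgroundModel, margin_mm: float
) -> None:
    clearance = 3.0 * model.psf_fwhm_mm
    for ax in range(3):
        lo = lesion.center[ax] - lesion.semi_axes[ax] - clearance
        hi = lesion.center[ax] + lesion.semi_axes[ax] + clearance
        if lo < 0 or hi > layout.extent_mm[ax]:
            raise GeometryError(
                f"lesion too close to the image border on axis {ax} "
                f"(needs {clearance:.1f} mm clearance)"
            )


def _voi_overlaps_block(voi: EllipsoidVOI, block: BoxROI) -> bool:
    # conservative separating-axis check between the VOI bounding box and the block
    for ax in range(3):
        voi_lo = voi.center[ax] - voi.semi_axes[ax]
        voi_hi = voi.center[ax] + voi.semi_axes[ax]
        blk_lo = block.center[ax] - block.edge_lengths[ax] / 2.0
        blk_hi = block.center[ax] + block.edge_lengths[ax] / 2.0
        if voi_hi < blk_lo or blk_hi < voi_lo:
            return False
    return True


def generate_case(
    lesion: LesionSpec,
    model: BackgroundModel,
    spacing: float = 2.0,
    seed: np.random.Generator | int = 0,
    *,
    layout: PhantomLayout = DEFAULT_LAYOUT,
    voi_margin_mm: float = 6.0,
    case_id: str = "case",
) -> PhantomCase:
    """Simulate one PET image: paint, blur, add noise; return the full case.

    Pipeline: soft tissue everywhere -> paint tissue blocks with their drawn
    SUVmean -> paint the lesion interior at ``peak_suv`` -> Gaussian blur at
    ``model.psf_fwhm_mm`` -> additive Gaussian noise (sd ``model.noise_sd``)
    truncated at zero.  The VOI is the lesion ellipsoid dilated by
    ``voi_margin_mm`` per axis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _check_lesion_fits(lesion, layout, model, voi_margin_mm)

    voi = EllipsoidVOI(
        lesion.center, tuple(a + voi_margin_mm for a in lesion.semi_axes)
    )
    for name, block in layout.blocks.items():
        if _voi_overlaps_block(voi, block):
            raise GeometryError(f"lesion VOI overlaps the {name} background block")

    suvs = sample_background_suvs(model, rng)
    shape = layout.grid_shape(spacing)
    grid = ScalarVolume(np.zeros(shape), (spacing,) * 3)

    values = np.full(shape, suvs["soft_tissue"], dtype=np.float64)
    for name, block in layout.blocks.items():
        values[rasterize(grid, block)] = suvs[name]
    values[rasterize(grid, EllipsoidVOI(lesion.center, lesion.semi_axes))] = lesion.peak_suv

    if model.psf_fwhm_mm > 0:
        sigma_vox = model.psf_fwhm_mm / _FWHM_TO_SIGMA / spacing
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if model.noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, model.noise_sd, shape), 0.0, None)

    pet = ScalarVolume(values, (spacing,) * 3)
    return PhantomCase(
        case_id=case_id,
        pet=pet,
        voi=voi,
        ct_reference_volume_ml=lesion.volume_ml,
        background_suvs={k: suvs[k] for k in ("liver", "parotis", "spleen")},
        rois=layout.rois(),
        lesion=lesion,
    )


def _sample_lesion(config: CohortConfig, rng: np.random.Generator) -> LesionSpec:
    lo, hi = config.volume_range_ml
    while True:
        vol_ml = float(
            rng.lognormal(math.log(config.volume_median_ml), config.volume_log_sd)
        )
        if lo <= vol_ml <= hi:
            break
    a_lo, a_hi = config.aspect_range
    while True:
        f1, f2 = rng.uniform(a_lo, a_hi, size=2)
        base = (vol_ml * 1000.0 * 3.0 / (4.0 * math.pi * f1 * f2)) ** (1.0 / 3.0)
        semi = np.array([base * f1, base * f2, base])
        if semi.min() >= 5.0:
            break
    semi = semi[rng.permutation(3)]
    peak = float(rng.uniform(*config.peak_suv_range))
    return LesionSpec(config.layout.lesion_center, tuple(semi), peak)


def generate_cohort(config: CohortConfig) -> list[PhantomCase]:
    """Generate ``config.n_cases`` reproducible phantom cases.

    Each case uses a substream seeded from ``(config.seed, case index)`` so a
    cohort is reproducible case-by-case regardless of cohort size.
    """
    cases = []
    for i in range(config.n_cases):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        )
        lesion = _sample_lesion(config, rng)
        cases.append(
            generate_case(
                lesion,
                config.background,
                spacing=config.spacing_mm,
                seed=rng,
                layout=config.layout,
                voi_margin_mm=config.voi_margin_mm,
                case_id=f"case_{i:03d}",
            )
        )
    return cases


def cohort_truth_table(cases: list[PhantomCase]):
    """Ground-truth table: case id, reference volume, background truths, peak."""
    import pandas as pd

    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "ct_reference_volume_ml": [c.ct_reference_volume_ml for c in cases],
            "suv_liver": [c.background_suvs["liver"] for c in cases],
            "suv_parotis": [c.background_suvs["parotis"] for c in cases],
            "suv_spleen": [c.background_suvs["spleen"] for c in cases],
            "peak_suv": [c.lesion.peak_suv for c in cases],
            "semi_axis_x_mm": [c.lesion.semi_axes[0] for c in cases],
            "semi_axis_y_mm": [c.lesion.semi_axes[1] for c in cases],
            "semi_axis_z_mm": [c.lesion.semi_axes[2] for c in cases],
        }
    )
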