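"""Threshold-based tumor delineation on PET.

Five segmentation families, all reducible to "count VOI voxels with
SUV >= t" for an absolute threshold t:

* ``fixed``       — t is an absolute SUV (e.g. SUV 4.0);
* ``isocontour``  — t = fraction x SUVmax inside the VOI;
* ``liver_rel``, ``parotis_rel``, ``spleen_rel``
                  — t = fraction x the reference tissue's SUVmean.

The threshold rule is inclusive (SUV >= t), so a 100% isocontour is never
empty and the inverse solver below operates on a well-defined finite
candidate set.  By default every suprathreshold voxel inside the VOI counts,
with no connectivity requirement — the VOI itself is assumed to exclude
off-target avid structures; an optional connected-component mode
(26-connectivity, component containing the VOI maximum) is available.

:func:`backwards_threshold` is the per-lesion inverse problem: find the
threshold whose segmented volume best matches a target (reference) volume.
Candidate thresholds are the unique voxel SUVs inside the VOI; volume(t) is
a non-increasing step function on that set, and ties in |volume - target|
are broken toward the larger threshold (the smaller volume).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

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
    "DelineationResult",
    "BackwardsThresholdResult",
    "suv_max_in_voi",
    "roi_mean",
    "segment_fixed",
    "segment_isocontour",
    "segment_background_relative",
    "backwards_threshold",
    "whole_image_fixed",
]

METHODS = ("fixed", "isocontour", "liver_rel", "parotis_rel", "spleen_rel")


@dataclass(frozen=True)
class DelineationResult:
    """One segmentation: the method, the absolute threshold applied, the volume."""

    case_id: str
    method: str
    level: float  # grid value: SUV for 'fixed', fraction for relative methods
    threshold_suv: float
    n_voxels: int
    volume_ml: float


@dataclass(frozen=True)
class BackwardsThresholdResult:
    """Per-lesion inverse solve: threshold whose volume best matches the target."""

    case_id: str
    threshold_suv: float
    achieved_volume_ml: float
    target_volume_ml: float


def suv_max_in_voi(pet: ScalarVolume, voi: EllipsoidVOI) -> float:
    """Maximum voxel SUV among voxels whose centers lie inside the VOI."""
    return float(pet.values[rasterize(pet, voi)].max())


def roi_mean(pet: ScalarVolume, roi: BoxROI | DiscROI) -> float:
    """Arithmetic mean SUV over the rasterized reference ROI."""
    return float(pet.values[rasterize(pet, roi)].mean())


def _count_component(pet: ScalarVolume, seg: np.ndarray, voi_mask: np.ndarray) -> np.ndarray:
    """Restrict ``seg`` to the 26-connected component containing the VOI max."""
    if not seg.any():
        return seg
    labels, _ = ndimage.label(seg, structure=np.ones((3, 3, 3), dtype=int))
    masked = np.where(voi_mask, pet.values, -np.inf)
    peak = np.unravel_index(int(np.argmax(masked)), pet.shape)
    target = labels[peak]
    if target == 0:
        # the VOI max itself fell below threshold; keep nothing
        return np.zeros_like(seg)
    return labels == target


def _segment(
    pet: ScalarVolume,
    voi: EllipsoidVOI,
    threshold_suv: float,
    method: str,
    level: float,
    case_id: str,
    connected: bool,
) -> DelineationResult:
    voi_mask = rasterize(pet, voi)
    seg = voi_mask & (pet.values >= threshold_suv)
    if connected:
        seg = _count_component(pet, seg, voi_mask)
    n = int(seg.sum())
    return DelineationResult(
        case_id=case_id,
        method=method,
        level=float(level),
        threshold_suv=float(threshold_suv),
        n_voxels=n,
        volume_ml=n * pet.voxel_volume_ml,
    )


def segment_fixed(
    pet: ScalarVolume,
    voi: EllipsoidVOI,
    t: float,
    *,
    case_id: str = "",
    connected: bool = False,
) -> DelineationResult:
    """Fixed absolute SUV threshold: count VOI voxels with SUV >= t."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    return _segment(pet, voi, t, "fixed", t, case_id, connected)


def segment_isocontour(
    pet: ScalarVolume,
    voi: EllipsoidVOI,
    fraction: float,
    *,
    case_id: str = "",
    connected: bool = False,
) -> DelineationResult:
    """Isocontour relative to the VOI's SUVmax: threshold = fraction x SUVmax."""
    if not (0 < fraction <= 1):
        raise ValueError("isocontour fraction must be in (0, 1]")
    t = fraction * suv_max_in_voi(pet, voi)
    return _segment(pet, voi, t, "isocontour", fraction, case_id, connected)


def segment_background_relative(
    pet: ScalarVolume,
    voi: EllipsoidVOI,
    background_suv: float,
    fraction: float,
    *,
    method: str = "liver_rel",
    case_id: str = "",
    connected: bool = False,
) -> DelineationResult:
    """Background-relative threshold: threshold = fraction x tissue SUVmean."""
    if background_suv <= 0:
        raise ValueError("background SUV must be positive")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if method not in ("liver_rel", "parotis_rel", "spleen_rel"):
        raise ValueError(f"unknown background-relative method {method!r}")
    t = fraction * background_suv
    return _segment(pet, voi, t, method, fraction, case_id, connected)


def backwards_threshold(
    pet: ScalarVolume,
    voi: EllipsoidVOI,
    target_volume_ml: float,
    *,
    case_id: str = "",
) -> BackwardsThresholdResult:
    """Per-lesion inverse solve over the finite set of attainable thresholds.

    Candidates are the unique voxel SUVs inside the VOI.  Returns the
    candidate minimizing |volume(t) - target|, ties broken toward the larger
    threshold.  Re-applying the returned threshold with
    :func:`segment_fixed` reproduces ``achieved_volume_ml`` exactly.
    """
    vals = pet.values[rasterize(pet, voi)]
    vv = pet.voxel_volume_ml
    full = vals.size * vv
    if not (0 < target_volume_ml <= full):
        raise ValueError(
            f"target volume {target_volume_ml} ml outside attainable range (0, {full}] ml"
        )
    sorted_vals = np.sort(vals)
    candidates = np.unique(vals)  # ascending
    counts = vals.size - np.searchsorted(sorted_vals, candidates, side="left")
    volumes = counts * vv
    diffs = np.abs(volumes - target_volume_ml)
    best = np.flatnonzero(diffs == diffs.min())[-1]  # last = largest threshold
    return BackwardsThresholdResult(
        case_id=case_id,
        threshold_suv=float(candidates[best]),
        achieved_volume_ml=float(volumes[best]),
        target_volume_ml=float(target_volume_ml),
    )


def whole_image_fixed(
    pet: ScalarVolume,
    t: float,
    exclusion_masks: Sequence[np.ndarray] = (),
) -> float:
    """Whole-image fixed-threshold tumor volume (ml), e.g. SUV 4.0 burden.

    Counts voxels with SUV >= t anywhere in the image outside the union of
    ``exclusion_masks`` (regions of physiological uptake to ignore).
    """
    excluded = np.zeros(pet.shape, dtype=bool)
    for mask in exclusion_masks:
        mask = np.asarray(mask)
        if mask.shape != pet.shape:
            raise GeometryError(
                f"exclusion mask shape {mask.shape} does not match image {pet.shape}"
            )
        excluded |= mask.astype(bool)
    n = int(((pet.values >= t) & ~excluded).sum())
    return n * pet.voxel_volume_ml
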